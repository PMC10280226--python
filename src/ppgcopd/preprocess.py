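"""Denoising, sub-band decomposition, epoching and spectral diagnostics.

The raw PPG is cleaned with a zero-phase Chebyshev type-II bandpass
(0.1-20 Hz) followed by a centered moving average, then decomposed into
three sub-frequency bands:

========  ================  =========================================
band      passband (Hz)     physiological content
========  ================  =========================================
PPG       0.1 - 20          denoised pulse waveform
LF        0.04 - 0.15       sympathetic / thermoregulatory component
MF        0.09 - 0.15       baroreflex (Mayer-wave) component
HF        0.15 - 6          cardiac pulse and respiratory component
========  ================  =========================================

The LF and MF bands overlap by construction; both are kept as defined.
All four signals are cut into aligned, non-overlapping 2-second epochs,
the unit of feature extraction and classification.

Chebyshev type-II design detail: scipy's ``Wn`` parametrizes the *stopband*
edges, where attenuation first reaches ``rs``. The band edges above are
passband edges, so the stopband edges are placed a transition ratio
(default 2x) outward on each side; with order 4 this keeps in-band gain
within a fraction of a percent of unity while the stopband floor sits at
``rs`` dB (doubled by forward-backward filtering). The narrow LF/MF bands
stay numerically stable because the filters are built and applied in
second-order-section form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import NyquistViolation, TooShort
from .records import PpgRecord

#: fixed band edges (Hz), keyed by band name
BAND_EDGES = {
    "PPG": (0.1, 20.0),
    "LF": (0.04, 0.15),
    "MF": (0.09, 0.15),
    "HF": (0.15, 6.0),
}

BANDS = ("PPG", "LF", "MF", "HF")

EPOCH_LEN_S = 2.0


@dataclass
class FilterSpec:
    """Specification of one denoising stage."""

    kind: str = "cheby2_bandpass"  # or "moving_average"
    low_hz: float = 0.1
    high_hz: float = 20.0
    order: int = 4
    stop_atten_db: float = 40.0
    transition_ratio: float = 2.0
    window_samples: int = 5
    zero_phase: bool = True

    def __post_init__(self):
        if self.kind == "cheby2_bandpass":
            if not (0 < self.low_hz < self.high_hz):
                raise ValueError("need 0 < low_hz < high_hz")
            if self.stop_atten_db <= 0:
                raise ValueError("stop_atten_db must be positive")
            if self.order < 2 or self.order % 2:
                raise ValueError("order must be even and >= 2")
        elif self.kind == "moving_average":
            if self.window_samples < 1 or self.window_samples % 2 == 0:
                raise ValueError("window_samples must be odd and >= 1")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


DEFAULT_BANDPASS = FilterSpec(kind="cheby2_bandpass", low_hz=0.1, high_hz=20.0)
DEFAULT_SMOOTHER = FilterSpec(kind="moving_average", window_samples=5)


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if spec.high_hz >= nyq:
        raise NyquistViolation(
            f"passband edge {spec.high_hz} Hz requires fs > {2 * spec.high_hz} Hz")
    stop_lo = spec.low_hz / spec.transition_ratio
    stop_hi = min(spec.high_hz * spec.transition_ratio, 0.99 * nyq)
    return sps.cheby2(spec.order, spec.stop_atten_db, [stop_lo, stop_hi],
                      btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Chebyshev-II bandpass; output length equals input length.

    Reflect padding of 3x the section count per edge absorbs the filter
    transient before sosfiltfilt's own edge handling.
    """
    x = np.asarray(x, dtype=float)
    sos = _design_sos(spec, fs)
    if x.size < 3 * spec.order:
        raise TooShort(
            f"signal of {x.size} samples too short for order-{spec.order} filter")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with edge replication; length preserved."""
    x = np.asarray(x, dtype=float)
    w = int(window_samples)
    if w == 1:
        return x.copy()
    half = w // 2
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def denoise(record: PpgRecord,
            bandpass: FilterSpec = DEFAULT_BANDPASS,
            smoother: FilterSpec = DEFAULT_SMOOTHER) -> np.ndarray:
    """Clean the raw PPG: bandpass to 0.1-20 Hz, then moving-average smooth.

    Order of stages follows the acquisition convention: wide bandpass first
    (removes DC drift and out-of-band noise), then the short moving average
    suppresses residual high-frequency ripple. Note the moving average has
    its own sinc-shaped response, so in-band tones near the upper passband
    edge are attenuated by its window gain as well.
    """
    y = bandpass_filter(record.samples, record.fs, bandpass)
    if smoother is not None and smoother.kind == "moving_average":
        y = moving_average(y, smoother.window_samples)
    elif smoother is not None:
        y = bandpass_filter(y, record.fs, smoother)
    return y


@dataclass
class BandSet:
    """The four aligned signals derived from one record."""

    ppg: np.ndarray
    lf: np.ndarray
    mf: np.ndarray
    hf: np.ndarray
    fs: float
    band_edges: dict = field(default_factory=lambda: dict(BAND_EDGES))

    def __post_init__(self):
        n = len(self.ppg)
        if not (len(self.lf) == len(self.mf) == len(self.hf) == n):
            raise ValueError("all four band signals must share one length")

    def as_array(self) -> np.ndarray:
        """Stack to shape (4, n) in fixed band order PPG, LF, MF, HF."""
        return np.stack([self.ppg, self.lf, self.mf, self.hf])


def decompose_bands(clean: np.ndarray, fs: float, order: int = 4,
                    stop_atten_db: float = 40.0,
                    transition_ratio: float = 2.0) -> BandSet:
    """Split a denoised signal into the LF/MF/HF bands (PPG slot = input)."""
    clean = np.asarray(clean, dtype=float)
    out = {"PPG": clean}
    for band in ("LF", "MF", "HF"):
        lo, hi = BAND_EDGES[band]
        spec = FilterSpec(kind="cheby2_bandpass", low_hz=lo, high_hz=hi,
                          order=order, stop_atten_db=stop_atten_db,
                          transition_ratio=transition_ratio)
        out[band] = bandpass_filter(clean, fs, spec)
    return BandSet(ppg=out["PPG"], lf=out["LF"], mf=out["MF"], hf=out["HF"],
                   fs=fs)


@dataclass
class EpochSet:
    """Aligned fixed-length epochs of the four band signals.

    ``epochs`` has shape (n_epochs, 4, samples_per_epoch); axis 1 follows
    the fixed band order PPG, LF, MF, HF.
    """

    epochs: np.ndarray
    epoch_len_s: float
    fs: float
    subject_id: str
    label: str

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


def epoch(bands: BandSet, epoch_len_s: float = EPOCH_LEN_S,
          subject_id: str = "", label: str = "UNKNOWN") -> EpochSet:
    """Cut all four bands into non-overlapping epochs at shared boundaries.

    The trailing partial epoch is discarded: n_epochs = floor(L / (T*fs)).
    """
    arr = bands.as_array()
    spe = round(epoch_len_s * bands.fs)
    n = arr.shape[1] // spe
    if n < 1:
        raise TooShort(
            f"signal of {arr.shape[1]} samples shorter than one "
            f"{epoch_len_s}-s epoch ({spe} samples)")
    cut = arr[:, : n * spe].reshape(4, n, spe).transpose(1, 0, 2)
    return EpochSet(epochs=np.ascontiguousarray(cut), epoch_len_s=epoch_len_s,
                    fs=bands.fs, subject_id=subject_id, label=label)


def periodogram(x: np.ndarray, fs: float):
    """One-sided FFT periodogram (boxcar window): (freqs Hz, PSD).

    The mean is removed first, so integrating the PSD over frequency
    recovers the signal variance exactly (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise TooShort("periodogram needs at least 8 samples")
    return sps.periodogram(x, fs=fs, window="boxcar", detrend="constant")
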