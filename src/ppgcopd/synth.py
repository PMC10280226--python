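"""Seeded synthetic PPG cohorts with a controllable COPD-vs-healthy effect.

The clinical recordings the method was designed for are not publicly
deposited, so this generator provides a stand-in cohort on which every
pipeline stage is testable. It is a signal-level emulation, NOT a
physiologically validated COPD waveform model.

Per subject, the signal is a quasi-periodic pulse train:

* each beat is two Gaussian bumps — a systolic peak (amplitude a1, offset
  0.30 T, width 0.10 T) and a dicrotic wave (0.4 a1 at 0.65 T, width
  0.12 T) — at the subject's mean beat period T with ~3% cycle jitter;
* the train is amplitude-modulated by respiration
  (1 + 0.2 sin(2 pi f_resp t)), a 0.05 Hz baseline wander of amplitude
  0.3 a1 is added, and white Gaussian instrument noise of sd ``noise_sd``
  (in units of the nominal pulse amplitude; sensor noise does not track
  the subject's perfusion) on top;
* beat-to-beat physiological variability: each beat's amplitude carries
  independent log-normal variation (sd ``beat_amp_sd``);
* subject-level random effects: heart rate ~ N(75, 8) bpm truncated to
  [50, 110], respiratory rate ~ U(0.2, 0.35) Hz, pulse amplitude
  a1 ~ LogNormal(0, 0.15), random phases;
* within-subject nonstationarity: the beat period drifts slowly (AR(1)
  beat-to-beat process, ~30 s time constant) and the whole optical signal
  is scaled by a continuous log-normal perfusion drift (AR(1), ~60 s),
  emulating the heart-rate wander and perfusion/coupling drift seen in
  real multi-minute recordings.

The class effect with size ``delta``: COPD subjects have pulse amplitude
scaled by (1 - 0.15 delta), cycle jitter scaled by (1 + 0.5 delta) and
noise sd scaled by (1 + 0.5 delta) — weaker, more irregular, noisier
pulses. delta = 0 makes the class-conditional signal distributions
identical by construction.

Demographics are drawn from the reference clinical cohort's distributions
(age 53.50 +/- 8.82 yr, weight 102.43 +/- 7.75 kg, height 172.93 +/- 6.43
cm, 12/14 male). Every record is fully determined by (seed, subject_index,
class).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import TooShort
from .records import COPD, HEALTHY, Cohort, PpgRecord, write_manifest, write_record

# Table-like calibration of the demographics generator (mean, sd)
_DEMOGRAPHICS = {"age": (53.50, 8.82), "weight": (102.43, 7.75),
                 "height": (172.93, 6.43)}
_P_MALE = 12.0 / 14.0


@dataclass
class CohortSpec:
    """Study-condition parameters of one synthetic cohort."""

    n_copd: int = 10
    n_healthy: int = 10
    duration_s: float = 300.0
    fs: float = 100.0
    heart_rate_mean_bpm: float = 75.0
    heart_rate_sd_bpm: float = 8.0
    resp_rate_range_hz: tuple[float, float] = (0.2, 0.35)
    baseline_wander_hz: float = 0.05
    noise_sd: float = 0.7           # instrument noise, nominal-amplitude units
    effect_size: float = 3.0        # delta; 0 = null construction
    amplitude_sd_log: float = 0.15  # subject-level LogNormal spread of a1
    jitter_frac: float = 0.03       # per-cycle period jitter, fraction of T
    beat_amp_sd: float = 0.15       # white beat-to-beat amplitude variation
    hr_drift_sd: float = 0.0        # optional slow beat-period drift (off:
    hr_drift_tau_s: float = 30.0    # slow drift leaks through temporal
    amp_drift_sd: float = 0.0       # adjacency under epoch-random splits)
    amp_drift_tau_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_copd < 1 or self.n_healthy < 1:
            raise ValueError("subject counts must be >= 1")
        if self.duration_s < 4:
            raise ValueError("duration_s must be >= 4")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _subject_rng(spec: CohortSpec, subject_index: int, cls: str):
    return np.random.default_rng(
        [spec.seed, subject_index, 1 if cls == COPD else 0])


def _ar1_series(rng, n: int, sd: float, tau_samples: float) -> np.ndarray:
    """Stationary zero-mean AR(1) sample path of length n, marginal sd *sd*."""
    from scipy.signal import lfilter
    rho = float(np.exp(-1.0 / tau_samples))
    eps = rng.standard_normal(n)
    x0 = eps[0]  # already unit-variance: the stationary marginal
    out, _ = lfilter([np.sqrt(1.0 - rho ** 2)], [1.0, -rho], eps[1:],
                     zi=[rho * x0])
    return sd * np.concatenate([[x0], out])


def simulate_record(spec: CohortSpec, subject_index: int, cls: str) -> PpgRecord:
    """One subject's record, fully determined by (seed, subject_index, class)."""
    rng = _subject_rng(spec, subject_index, cls)
    delta = spec.effect_size

    hr = np.clip(rng.normal(spec.heart_rate_mean_bpm, spec.heart_rate_sd_bpm),
                 50.0, 110.0)
    period = 60.0 / hr
    resp = rng.uniform(*spec.resp_rate_range_hz)
    a1 = float(np.exp(rng.normal(0.0, spec.amplitude_sd_log)))
    phase_resp = rng.uniform(0, 2 * np.pi)
    phase_bw = rng.uniform(0, 2 * np.pi)

    jitter = spec.jitter_frac
    noise_sd = spec.noise_sd
    if cls == COPD:
        a1 *= max(1.0 - 0.15 * delta, 0.05)
        jitter *= 1.0 + 0.5 * delta
        noise_sd *= 1.0 + 0.5 * delta

    n = round(spec.duration_s * spec.fs)
    if spec.duration_s < 3 * period:
        raise TooShort("duration must cover at least 3 beats")
    t = np.arange(n) / spec.fs
    x = np.zeros(n)

    # beat train: sequential onsets with jittered, slowly drifting periods
    onset = float(rng.uniform(0, period))  # random initial beat phase
    rho_hr = float(np.exp(-period / spec.hr_drift_tau_s))
    hr_state = spec.hr_drift_sd * rng.standard_normal()
    while onset < spec.duration_s + period:
        hr_state = (rho_hr * hr_state
                    + np.sqrt(1 - rho_hr ** 2) * spec.hr_drift_sd
                    * rng.standard_normal())
        T = period * (1.0 + hr_state + jitter * rng.standard_normal())
        T = max(T, 0.3 * period)
        a_beat = a1 * float(np.exp(spec.beat_amp_sd * rng.standard_normal()))
        for amp, off_frac, width_frac in ((a_beat, 0.30, 0.10),
                                          (0.4 * a_beat, 0.65, 0.12)):
            center = onset + off_frac * T
            sigma = width_frac * T
            lo = max(int((center - 4 * sigma) * spec.fs), 0)
            hi = min(int((center + 4 * sigma) * spec.fs) + 1, n)
            if lo < hi:
                seg = t[lo:hi]
                x[lo:hi] += amp * np.exp(-0.5 * ((seg - center) / sigma) ** 2)
        onset += T

    x *= 1.0 + 0.2 * np.sin(2 * np.pi * resp * t + phase_resp)
    x += 0.3 * a1 * np.sin(2 * np.pi * spec.baseline_wander_hz * t + phase_bw)
    # continuous perfusion drift scales the whole optical signal
    x *= np.exp(_ar1_series(rng, n, spec.amp_drift_sd,
                            spec.amp_drift_tau_s * spec.fs))
    x += rng.normal(0.0, noise_sd, size=n)

    age = rng.normal(*_DEMOGRAPHICS["age"])
    weight = rng.normal(*_DEMOGRAPHICS["weight"])
    height = rng.normal(*_DEMOGRAPHICS["height"])
    sex = "M" if rng.uniform() < _P_MALE else "F"

    return PpgRecord(
        subject_id=f"S{subject_index:03d}_{'copd' if cls == COPD else 'ctrl'}",
        samples=x, fs=spec.fs, label=cls,
        age=float(age), weight=float(weight), height=float(height), sex=sex)


def simulate_cohort(spec: CohortSpec, out_dir=None, fmt: str = "csv") -> Cohort:
    """All n_copd + n_healthy records (COPD first); optionally written to disk.

    With *out_dir*, each record is written in *fmt* plus a ``manifest.csv``
    readable by :func:`ppgcopd.records.load_cohort`.
    """
    records = []
    idx = 0
    for _ in range(spec.n_copd):
        records.append(simulate_record(spec, idx, COPD))
        idx += 1
    for _ in range(spec.n_healthy):
        records.append(simulate_record(spec, idx, HEALTHY))
        idx += 1
    cohort = Cohort(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for rec in records:
            p = out / f"{rec.subject_id}.{fmt}"
            write_record(rec, p, format=fmt)
            paths.append(p.name)
        write_manifest(cohort, paths, out / "manifest.csv")
    return cohort
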