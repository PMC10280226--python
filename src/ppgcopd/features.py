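"""The 25 time-domain epoch descriptors and feature-matrix assembly.

Each 2-second epoch of each band signal is summarized by 25 statistics.
The numbering and the exact printed formula conventions are fixed:

====  ==============  ====================================================
 #    short name      definition (x = epoch, n = length, S = sample sd)
====  ==============  ====================================================
 1    kurtosis        sum((x-mean)^4) / ((n-1) S^4)
 2    skewness        sum((x-mean)^3) / ((n-1) S^3)
 3    iqr             interquartile range (Hazen quantiles, (i-0.5)/n)
 4    cv              coefficient of variation, (S / mean) * 100
 5    geo_mean        geometric mean of |x| (log-mean; |x| floored at 1e-12)
 6    harm_mean       harmonic mean of |x| (floored at 1e-12)
 7    activity        Hjorth activity, S^2
 8    mobility        Hjorth mobility as a VARIANCE ratio S1^2 / S^2
 9    complexity      sqrt((S2^2/S1^2)^2 - (S1^2/S^2)^2), radicand clamped
10    max             maximum
11    median          median
12    mad             mean absolute deviation about the mean
13    min             minimum
14    cmoment10       10th central moment, 1/n normalization
15    mean            arithmetic mean
16    curve_length    (1/n) sum_{i=2..n} |x_i - x_{i-1}|
17    energy          (1/n) sum x_i^2
18    rms             sqrt(energy)
19    std_err         S / sqrt(n)
20    std             S (n-1 denominator)
21    shape_factor    rms / ((1/n) sum sqrt(|x_i|))
22    svd             the single singular value of the epoch = 2-norm
23    trim_mean25     25% trimmed mean (round(n*25/200) cut per tail)
24    trim_mean50     50% trimmed mean
25    teager          (1/n) sum_{i=3..n} (x_{i-1}^2 - x_i * x_{i-2})
====  ==============  ====================================================

S1^2 and S2^2 are the sample variances of the first and second difference
signals (plain differences, no fs scaling). Mobility is deliberately the
printed variance ratio, not the conventional square root. Kurtosis and
skewness use the printed (n-1)-denominator convention rather than the
bias-corrected textbook estimators.

Bandpassed signals are near zero-mean, so the coefficient of variation can
blow up and the geometric/harmonic means are undefined on signed data; the
former is sanitized (non-finite -> 0, cell flagged), the latter two are
taken over magnitudes with a 1e-12 floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateEpoch, ManifestMismatch, TooShort
from .preprocess import BANDS, EpochSet
from .records import COPD, Cohort

_EPS = 1e-12

FEATURE_SHORTNAMES = (
    "kurtosis", "skewness", "iqr", "cv", "geo_mean", "harm_mean",
    "activity", "mobility", "complexity", "max", "median", "mad", "min",
    "cmoment10", "mean", "curve_length", "energy", "rms", "std_err", "std",
    "shape_factor", "svd", "trim_mean25", "trim_mean50", "teager",
)

FEATURE_NAMES = tuple(
    f"f{i + 1:02d}_{name}" for i, name in enumerate(FEATURE_SHORTNAMES))

N_FEATURES = 25

DEMO_COLUMNS = ("demo/age", "demo/weight", "demo/height")


def band_columns(band: str) -> list[str]:
    """The 25 feature column names of one band, in fixed order."""
    return [f"{band}/{name}" for name in FEATURE_NAMES]


def all_signal_columns() -> list[str]:
    return [c for band in BANDS for c in band_columns(band)]


def trimmed_mean(x: np.ndarray, percent: float) -> float:
    """Trimmed mean cutting round(n * percent/200) values from each tail.

    ``round`` is half-away-from-zero, matching the convention of numeric
    environments that define trimmean this way.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    k = int(np.floor(n * percent / 200.0 + 0.5))
    if n - 2 * k < 1:
        raise DegenerateEpoch(
            f"trimming {k} per tail leaves no samples out of {n}")
    return float(np.mean(x[k: n - k]))


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth (activity, mobility, complexity) with the printed conventions.

    Raises DegenerateEpoch on a constant epoch (S = 0). A zero-variance
    first difference (e.g. a linear ramp) gives mobility 0 and complexity 0
    via the radicand clamp.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise TooShort("Hjorth parameters need n >= 4")
    s2 = float(np.var(x, ddof=1))
    if s2 == 0.0:
        raise DegenerateEpoch("constant epoch: Hjorth parameters undefined")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    s1sq = float(np.var(d1, ddof=1))
    s2sq = float(np.var(d2, ddof=1))
    mobility = s1sq / s2
    if s1sq == 0.0:
        return s2, 0.0, 0.0
    radicand = (s2sq / s1sq) ** 2 - (s1sq / s2) ** 2
    complexity = float(np.sqrt(max(radicand, 0.0)))
    return s2, mobility, complexity


def _feature_block(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 25-feature extraction over rows of X (n_epochs, n).

    Returns (values of shape (n_epochs, 25), flagged boolean mask of cells
    that were non-finite before sanitization to 0).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (epochs x samples) array")
    m, n = X.shape
    if n < 4:
        raise TooShort(f"epochs of {n} samples; features need n >= 4")

    mean = X.mean(axis=1)
    dev = X - mean[:, None]
    S2 = (dev ** 2).sum(axis=1) / (n - 1)
    S = np.sqrt(S2)

    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.empty((m, N_FEATURES))
        out[:, 0] = (dev ** 4).sum(axis=1) / ((n - 1) * S ** 4)
        out[:, 1] = (dev ** 3).sum(axis=1) / ((n - 1) * S ** 3)
        q75, q25 = np.quantile(X, [0.75, 0.25], axis=1, method="hazen")
        out[:, 2] = q75 - q25
        out[:, 3] = S / mean * 100.0
        absx = np.maximum(np.abs(X), _EPS)
        out[:, 4] = np.exp(np.log(absx).mean(axis=1))
        out[:, 5] = n / (1.0 / absx).sum(axis=1)
        d1 = np.diff(X, axis=1)
        d2 = np.diff(d1, axis=1)
        s1sq = d1.var(axis=1, ddof=1)
        s2sq = d2.var(axis=1, ddof=1)
        out[:, 6] = S2
        out[:, 7] = s1sq / S2
        radicand = (s2sq / s1sq) ** 2 - (s1sq / S2) ** 2
        out[:, 8] = np.sqrt(np.maximum(radicand, 0.0))
        out[:, 8] = np.where(s1sq == 0.0, 0.0, out[:, 8])
        out[:, 9] = X.max(axis=1)
        out[:, 10] = np.median(X, axis=1)
        out[:, 11] = np.abs(dev).mean(axis=1)
        out[:, 12] = X.min(axis=1)
        out[:, 13] = (dev ** 10).mean(axis=1)
        out[:, 14] = mean
        out[:, 15] = np.abs(d1).sum(axis=1) / n
        energy = (X ** 2).mean(axis=1)
        out[:, 16] = energy
        rms = np.sqrt(energy)
        out[:, 17] = rms
        out[:, 18] = S / np.sqrt(n)
        out[:, 19] = S
        out[:, 20] = rms / np.sqrt(np.abs(X)).mean(axis=1)
        out[:, 21] = np.linalg.norm(X, axis=1)
        srt = np.sort(X, axis=1)
        for j, pct in ((22, 25.0), (23, 50.0)):
            k = int(np.floor(n * pct / 200.0 + 0.5))
            out[:, j] = srt[:, k: n - k].mean(axis=1)
        out[:, 24] = (X[:, 1:-1] ** 2 - X[:, 2:] * X[:, :-2]).sum(axis=1) / n

    flagged = ~np.isfinite(out)
    out[flagged] = 0.0
    return out, flagged


@dataclass
class FeatureVector:
    """25 named feature values for one epoch of one band signal."""

    values: np.ndarray
    band: str
    flagged: np.ndarray  # cells sanitized from non-finite to 0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def extract_features(epoch_samples: np.ndarray, band: str = "PPG") -> FeatureVector:
    """Compute the 25 descriptors for a single epoch."""
    values, flagged = _feature_block(np.atleast_2d(epoch_samples))
    return FeatureVector(values=values[0], band=band, flagged=flagged[0])


@dataclass
class FeatureMatrix:
    """Epochs-by-features table with labels and subject bookkeeping.

    ``data`` columns are named ``BAND/fNN_shortname`` (4 bands x 25 in band
    order PPG, LF, MF, HF) plus optional ``demo/age``, ``demo/weight``,
    ``demo/height``. Row order equals epoch order within subjects, subjects
    in cohort order.
    """

    data: pd.DataFrame
    labels: np.ndarray       # 1 = COPD, 0 = healthy
    subject_ids: np.ndarray
    flagged: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.data) != len(self.labels) or len(self.data) != len(self.subject_ids):
            raise ValueError("data, labels and subject_ids must align")

    def __len__(self):
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def pool_columns(self, pool: str) -> list[str]:
        """Column names of a feature pool: one band, or ALL = the 100."""
        if pool == "ALL":
            return [c for c in self.data.columns if not c.startswith("demo/")]
        if pool not in BANDS:
            raise ValueError(f"unknown pool {pool!r}")
        return [c for c in self.data.columns if c.startswith(pool + "/")]

    def to_csv(self, path) -> str:
        df = self.data.copy()
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, index=False, float_format="%.17g")
        return str(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        labels = df.pop("label").to_numpy(dtype=int)
        sids = df.pop("subject_id").to_numpy(dtype=str)
        return cls(data=df, labels=labels, subject_ids=sids)


def build_matrix(epoch_sets: list[EpochSet], cohort: Cohort | None = None,
                 include_demographics: bool = False) -> FeatureMatrix:
    """Assemble the labeled feature matrix from per-subject epoch sets.

    Per epoch: 25 features from each of the four band signals, concatenated
    in band order; demographics (if requested) are repeated across all of a
    subject's epochs.
    """
    if include_demographics and cohort is None:
        raise ManifestMismatch("demographics requested but no cohort given")
    blocks, labels, sids, flags = [], [], [], []
    columns = all_signal_columns()
    for es in epoch_sets:
        rec = None
        if cohort is not None:
            try:
                rec = cohort.by_id(es.subject_id)
            except KeyError:
                raise ManifestMismatch(
                    f"subject {es.subject_id!r} not in cohort") from None
        per_band = []
        per_band_flags = []
        for b in range(4):
            vals, flagged = _feature_block(es.epochs[:, b, :])
            per_band.append(vals)
            per_band_flags.append(flagged)
        block = np.hstack(per_band)
        flag = np.hstack(per_band_flags)
        df = pd.DataFrame(block, columns=columns)
        if include_demographics:
            for col, attr in zip(DEMO_COLUMNS, ("age", "weight", "height")):
                v = getattr(rec, attr)
                df[col] = np.nan if v is None else float(v)
        blocks.append(df)
        flags.append(pd.DataFrame(flag, columns=columns))
        labels.extend([1 if es.label == COPD else 0] * es.n_epochs)
        sids.extend([es.subject_id] * es.n_epochs)
    data = pd.concat(blocks, ignore_index=True)
    flagged = pd.concat(flags, ignore_index=True)
    return FeatureMatrix(data=data, labels=np.asarray(labels),
                         subject_ids=np.asarray(sids), flagged=flagged)
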