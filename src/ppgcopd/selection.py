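"""Fisher-score feature ranking, association level R, and selection levels.

Features are ranked within a pool (one band's 25 columns, or ALL = the 100
signal columns) by the Fisher criterion

    F_j = (mu_j1 - mu_j0)^2 / (s_j1^2 + s_j0^2)

with class-conditional sample means and variances. Alongside the score,
each feature's association level R is reported as the absolute
point-biserial correlation between the feature and the 0/1 label, with the
conventional strength bands (negligible < 0.2 <= weak < 0.4 <= moderate
< 0.7 <= strong < 0.9 <= very strong).

Ten nested selection levels take the top 5%, 10%, ..., 50% of the ranked
pool; subset sizes use ceil so even a 25-feature pool keeps at least one
feature at level 1 and grows monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .exceptions import BadLevel, BadValue, SingleClassError
from .features import FeatureMatrix

POOLS = ("PPG", "LF", "MF", "HF", "ALL")

R_BANDS = (
    (0.2, "negligible"),
    (0.4, "weak"),
    (0.7, "moderate"),
    (0.9, "strong"),
    (np.inf, "very strong"),
)


def interpret_R(r: float) -> str:
    """Map an association level R in [0, 1] to its strength label."""
    if not (0.0 <= r <= 1.0):
        raise BadValue(f"R must lie in [0, 1], got {r}")
    for upper, label in R_BANDS:
        if r < upper:
            return label
    return "very strong"  # pragma: no cover — inf band always matches


@dataclass
class FisherRanking:
    """Descending Fisher-score ranking of one pool's features.

    ``entries`` is a DataFrame with columns rank, feature_id, fisher_score,
    R, strength; ties in the score break by the pool's column order.
    """

    pool: str
    entries: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries["feature_id"])

    def to_csv(self, path) -> str:
        df = self.entries.copy()
        df.insert(0, "pool", self.pool)
        df.to_csv(path, index=False)
        return str(path)


def fisher_scores(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Fisher scores and |point-biserial| R for binary labels.

    Constant columns (zero pooled spread) score 0 with R 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError("Fisher ranking needs both classes present")
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    v0 = X[y == 0].var(axis=0, ddof=1)
    v1 = X[y == 1].var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (m1 - m0) ** 2 / (v0 + v1)
        yc = y - y.mean()
        xc = X - X.mean(axis=0)
        denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
        r = np.abs((xc * yc[:, None]).sum(axis=0) / denom)
    scores = np.where(np.isfinite(scores), scores, 0.0)
    r = np.where(np.isfinite(r), r, 0.0)
    return scores, np.clip(r, 0.0, 1.0)


def fisher_rank(matrix: FeatureMatrix, pool: str = "ALL",
                rows: np.ndarray | None = None) -> FisherRanking:
    """Rank a pool's features on the given rows (default: all rows).

    Pass the training-row indices to keep the ranking free of test-set
    leakage; pass nothing to reproduce a whole-dataset association table.
    """
    if pool not in POOLS:
        raise BadValue(f"pool must be one of {POOLS}, got {pool!r}")
    cols = matrix.pool_columns(pool)
    X = matrix.data[cols].to_numpy()
    y = matrix.labels
    if rows is not None:
        X, y = X[rows], y[rows]
    scores, r = fisher_scores(X, y)
    order = np.lexsort((np.arange(len(cols)), -scores))
    entries = pd.DataFrame({
        "rank": np.arange(1, len(cols) + 1),
        "feature_id": [cols[i] for i in order],
        "fisher_score": scores[order],
        "R": r[order],
        "strength": [interpret_R(v) for v in r[order]],
    })
    return FisherRanking(pool=pool, entries=entries)


@dataclass
class LevelSubset:
    """The top-fraction feature subset at one of the ten selection levels."""

    level: int
    pool: str
    feature_ids: list[str]

    @property
    def fraction(self) -> float:
        return 0.05 * self.level


def level_subset(ranking: FisherRanking, level: int) -> LevelSubset:
    """Top ceil(0.05 * level * pool_size) features; nested across levels."""
    if not (1 <= int(level) <= 10) or int(level) != level:
        raise BadLevel(f"level must be an integer in 1..10, got {level}")
    size = len(ranking.entries)
    k = ceil(0.05 * level * size)
    return LevelSubset(level=int(level), pool=ranking.pool,
                       feature_ids=ranking.feature_ids[:k])
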