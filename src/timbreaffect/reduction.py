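"""Collinearity analysis, descriptor pruning, adequacy and normalization.

Spectral descriptors computed from the same spectra are often nearly
collinear across a stimulus set (e.g. centroid with slope and rolloff).
Before regression modelling the descriptor set is therefore correlated
pairwise, clustered hierarchically (average linkage on the distance
``1 - |r|``), and pruned: of any pair with ``|r|`` above a threshold
(default 0.905) the member lower in a keep-priority list is dropped.
Sampling adequacy of the retained set is summarised by the
Kaiser-Meyer-Olkin index, and predictors are range-normalised to [0, 1]
for the downstream network model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .descriptors import CANONICAL_DESCRIPTORS

log = logging.getLogger(__name__)

PRUNE_THRESHOLD = 0.905

#: The canonical six removals of the 23 -> 17 reduction for orchestral-tone
#: descriptor sets: slope (median and IQR), spread median and rolloff median
#: are nearly collinear with the centroid measures, kurtosis with skewness.
REFERENCE_REMOVALS = ("spec_slope_med", "spec_slope_iqr", "spec_spread_med",
                      "spec_rolloff_med", "spec_kurtosis_med", "spec_kurtosis_iqr")

#: Default keep priority: every descriptor outranks the reference removals,
#: so data-driven pruning resolves those pairs the canonical way.
DEFAULT_KEEP_PRIORITY = [n for n in CANONICAL_DESCRIPTORS
                         if n not in REFERENCE_REMOVALS]


class ReductionError(ValueError):
    pass


def correlation_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of descriptor columns.

    Raises on constant columns (their correlation is undefined).
    """
    if len(X) < 3:
        raise ReductionError("need at least 3 stimuli")
    const = X.columns[X.std(ddof=0) == 0]
    if len(const):
        raise ReductionError(f"constant column(s): {', '.join(const)}")
    C = X.corr(method="pearson")
    np.fill_diagonal(C.values, 1.0)
    return C


def cluster_descriptors(C: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomerative tree on the distance ``1 - |r|``.

    Returns a scipy linkage matrix; merge heights are non-decreasing.
    Absolute correlation is used so anticorrelated near-duplicates also
    merge early.
    """
    D = 1.0 - np.abs(C.to_numpy())
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def dendrogram_text(C: pd.DataFrame) -> str:
    """Plain-text rendering of the merge order (height: members)."""
    Z = cluster_descriptors(C)
    names = list(C.columns)
    clusters = {i: [n] for i, n in enumerate(names)}
    lines = []
    for step, (a, b, h, _) in enumerate(Z):
        merged = clusters.pop(int(a)) + clusters.pop(int(b))
        clusters[len(names) + step] = merged
        lines.append(f"{h:6.3f}: {' + '.join(merged)}")
    return "\n".join(lines)


@dataclass
class ReductionReport:
    correlation: pd.DataFrame
    linkage: np.ndarray
    retained: list[str]
    removed: list[dict] = field(default_factory=list)
    kmo: float | None = None

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "removed": self.removed,
            "kmo": self.kmo,
            "n_retained": len(self.retained),
        }


def prune_collinear(C: pd.DataFrame, threshold: float = PRUNE_THRESHOLD,
                    keep_priority: list[str] | None = None
                    ) -> tuple[list[str], list[dict]]:
    """Iteratively drop one member of every pair with ``|r| > threshold``.

    The strongest-correlated offending pair is resolved first; the member
    ranked lower in ``keep_priority`` is removed (names absent from the
    list rank below all listed names; ties keep the alphabetically first).
    Deterministic, and idempotent on its own output.
    """
    if not (0.0 < threshold < 1.0):
        raise ReductionError("threshold must lie in (0, 1)")
    priority = DEFAULT_KEEP_PRIORITY if keep_priority is None else keep_priority

    def rank(name: str) -> tuple[int, str]:
        try:
            return (priority.index(name), name)
        except ValueError:
            return (len(priority), name)

    retained = list(C.columns)
    removed: list[dict] = []
    A = np.abs(C.to_numpy()).copy()
    np.fill_diagonal(A, 0.0)
    names = list(C.columns)
    alive = {n: True for n in names}
    while True:
        live_idx = [i for i, n in enumerate(names) if alive[n]]
        sub = A[np.ix_(live_idx, live_idx)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = names[live_idx[i]], names[live_idx[j]]
        drop, keep = (a, b) if rank(a) > rank(b) else (b, a)
        alive[drop] = False
        removed.append({"removed": drop, "kept": keep,
                        "r": float(C.loc[a, b])})
    retained = [n for n in names if alive[n]]
    return retained, removed


def kmo_index(X: pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy of a descriptor matrix.

    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over off-diagonal
    elements, where ``q`` are the anti-image partial correlations obtained
    from the inverse correlation matrix.  Scale-invariant; always 0.5 for
    exactly two variables.
    """
    C = correlation_matrix(X) if not _is_corr(X) else X
    R = C.to_numpy()
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ReductionError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(len(R), dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def _is_corr(X: pd.DataFrame) -> bool:
    return (X.shape[0] == X.shape[1]
            and list(X.index) == list(X.columns)
            and np.allclose(np.diag(X.to_numpy()), 1.0))


@dataclass
class RangeNormalizer:
    """Per-column (x - min) / (max - min) map with stored statistics.

    Fitted on training data; applying to held-out rows may produce values
    outside [0, 1] (logged, not clipped), as dictated by the training-fold
    statistics.
    """

    mins: pd.Series | None = None
    maxs: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "RangeNormalizer":
        span = X.max() - X.min()
        const = X.columns[span == 0]
        if len(const):
            raise ReductionError(f"constant column(s): {', '.join(const)}")
        self.mins, self.maxs = X.min(), X.max()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = (X - self.mins) / (self.maxs - self.mins)
        if (Z.to_numpy() < 0).any() or (Z.to_numpy() > 1).any():
            log.info("range-normalised values outside [0, 1] for held-out rows")
        return Z

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * (self.maxs - self.mins) + self.mins


def range_normalize(X: pd.DataFrame) -> tuple[pd.DataFrame, RangeNormalizer]:
    """Convenience: fit a :class:`RangeNormalizer` on ``X`` and apply it."""
    norm = RangeNormalizer().fit(X)
    return norm.transform(X), norm


def reduce_descriptors(X: pd.DataFrame, threshold: float = PRUNE_THRESHOLD,
                       keep_priority: list[str] | None = None,
                       removals: str = "reference") -> ReductionReport:
    """Full reduction pass: correlate, cluster, prune, and score adequacy.

    ``removals="reference"`` (default) drops the canonical
    :data:`REFERENCE_REMOVALS` present in ``X`` — the committed 23 -> 17
    reduction for this descriptor family; ``removals="data"`` prunes
    purely by the ``|r| > threshold`` rule, which on other stimulus sets
    may drop a different subset.
    """
    C = correlation_matrix(X)
    Z = cluster_descriptors(C)
    if removals == "reference":
        retained = [n for n in C.columns if n not in REFERENCE_REMOVALS]
        removed = [{"removed": n,
                    "kept": max(retained, key=lambda m: abs(C.loc[n, m])),
                    "r": float(C.loc[n, max(retained,
                                            key=lambda m: abs(C.loc[n, m]))])}
                   for n in C.columns if n in REFERENCE_REMOVALS]
    elif removals == "data":
        retained, removed = prune_collinear(C, threshold, keep_priority)
    else:
        raise ReductionError(f"unknown removals mode {removals!r}")
    kmo = kmo_index(X[retained]) if len(retained) >= 2 else None
    return ReductionReport(correlation=C, linkage=Z, retained=retained,
                           removed=removed, kmo=kmo)
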