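"""Beta-diversity distances, principal coordinates, PERMANOVA, and
stratified distance-group comparisons.

Three dissimilarities are supported, all bounded on [0, 1]:

* ``bray_curtis`` on relative abundances, sum|x - y| / sum(x + y);
* ``jaccard`` (unweighted) on presence/absence;
* ``jensen_shannon``: the square root of the Jensen-Shannon divergence
  with base-2 logarithms, which is a metric with maximum 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import FeatureTable

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "PCoAResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "permanova_factors",
    "DistanceGroups",
    "distance_groups",
]

METRICS = ("bray_curtis", "jaccard", "jensen_shannon")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample dissimilarity matrix."""

    data: np.ndarray
    ids: list[str]
    metric: str = "bray_curtis"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def between(self, i, j) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.data[a, b])

    def filter(self, ids) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(self.data[np.ix_(pos, pos)], list(ids), self.metric)


def pairwise_distances(relabund: FeatureTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """All pairwise dissimilarities between samples of a proportion table."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = relabund.counts.to_numpy(dtype=float).T  # samples x SVs
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if metric == "jaccard":
        vec = pdist(X > 0, metric="jaccard")
    elif metric == "bray_curtis":
        if not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("columns must sum to 1 (relative abundances)")
        vec = pdist(X, metric="braycurtis")
    else:
        if not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("columns must sum to 1 (relative abundances)")
        # scipy's jensenshannon distance uses natural logs; rescale so the
        # base-2 form has maximum exactly 1
        vec = pdist(X, metric="jensenshannon") / math.sqrt(math.log(2.0))
    mat = squareform(np.clip(vec, 0.0, 1.0))
    return DistanceMatrix(mat, list(relabund.sample_ids), metric)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # samples x axes
    proportion_explained: np.ndarray
    eigenvalues: np.ndarray         # all eigenvalues, descending


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Gower double-centering of -D^2/2 followed by eigendecomposition; axes
    come from positive eigenvalues sorted descending, and the proportion
    explained divides by the sum of positive eigenvalues.  Negative
    eigenvalues are reported untouched.
    """
    D2 = dm.data ** 2
    n = dm.n
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if evals.size else 0.0
    pos = evals > tol
    if not pos.any():
        raise ValueError("no positive eigenvalues; distances carry no metric structure")
    k = int(pos.sum()) if n_axes is None else min(n_axes, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    frame = pd.DataFrame(coords, index=dm.ids,
                         columns=[f"PC{i+1}" for i in range(k)])
    prop = evals[:k] / evals[pos].sum()
    return PCoAResult(coordinates=frame, proportion_explained=prop,
                      eigenvalues=evals)


@dataclass
class PermanovaResult:
    factor: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int
    degenerate: bool = False   # zero within-group sum of squares


def _ss_parts(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = len(codes)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def _pseudo_f(ss_total, ss_within, n, a):
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame, factor: str,
              n_permutations: int | None = 999,
              seed: int | np.random.Generator = 0) -> PermanovaResult:
    """One-way PERMANOVA with label-permutation significance.

    ``R^2 = 1 - SS_within / SS_total`` partitions the squared-distance
    variance; the p value uses the +1 correction, so it can never be
    exactly zero.  ``n_permutations=None`` enumerates every distinct label
    arrangement exactly (small n only) and reports the exact fraction.
    """
    groups = metadata.loc[dm.ids, factor].to_numpy()
    labels, codes = np.unique(groups, return_inverse=True)
    a, n = len(labels), dm.n
    if a < 2:
        raise ValueError("need at least 2 groups")
    D2 = dm.data ** 2
    ss_total, ss_within = _ss_parts(D2, codes, a)
    if ss_total == 0:
        raise ValueError("all distances are zero")
    r2 = 1.0 - ss_within / ss_total
    f_obs = _pseudo_f(ss_total, ss_within, n, a)

    if n_permutations is None:
        distinct = set(itertools.permutations(codes))
        if len(distinct) > 500_000:  # pragma: no cover - guard
            raise ValueError("exhaustive enumeration infeasible at this size")
        hits = total = 0
        for perm in distinct:
            _, ssw = _ss_parts(D2, np.asarray(perm), a)
            if _pseudo_f(ss_total, ssw, n, a) >= f_obs:
                hits += 1
            total += 1
        p = hits / total
        n_perm = total
    else:
        if n_permutations < 99:
            raise ValueError("use at least 99 permutations")
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
        ssw_perm = np.zeros(n_permutations)
        for g in range(a):
            Z = (perms == g).astype(float)
            n_g = int((codes == g).sum())
            if n_g > 1:
                ssw_perm += np.einsum("pi,pi->p", Z @ D2, Z) / (2.0 * n_g)
        ss_between = ss_total - ssw_perm
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = np.where(ssw_perm == 0, math.inf,
                              (ss_between / (a - 1)) / (ssw_perm / (n - a)))
        p = (1.0 + int((f_perm >= f_obs).sum())) / (1.0 + n_permutations)
        n_perm = n_permutations
    return PermanovaResult(factor=factor, r_squared=float(r2),
                           pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=int(n_perm), n_samples=n,
                           n_groups=a, degenerate=ss_within == 0)


def permanova_factors(dm: DistanceMatrix, metadata: pd.DataFrame, factors,
                      n_permutations: int = 999, seed: int = 0) -> dict:
    """Sequential single-factor PERMANOVAs (each factor tested marginally)."""
    rng = np.random.default_rng(seed)
    return {f: permanova(dm, metadata, f, n_permutations, rng) for f in factors}


@dataclass
class DistanceGroups:
    """Pairwise distances partitioned into technical and biological sets."""

    groups: dict[str, np.ndarray] = field(default_factory=dict)
    empty: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.groups.items():
            rows.append(dict(group=name, n_pairs=len(vals),
                             mean=float(np.mean(vals)) if len(vals) else np.nan,
                             median=float(np.median(vals)) if len(vals) else np.nan))
        return pd.DataFrame(rows).set_index("group")


def distance_groups(dm: DistanceMatrix, metadata: pd.DataFrame) -> DistanceGroups:
    """Partition pairwise distances among specimen-labelled samples.

    Pairs sharing a specimen split into intra-run vs. inter-run (technical
    variation); pairs of different specimens form the biological set.
    Samples without a specimen id are ignored.  Empty partitions are
    flagged, not fatal.
    """
    md = metadata.loc[dm.ids]
    has_spec = md["specimen_id"].notna()
    ids = [s for s, ok in zip(dm.ids, has_spec) if ok]
    sets: dict[str, list] = {"intra_run": [], "inter_run": [], "biological": []}
    for i, j in itertools.combinations(ids, 2):
        d = dm.between(i, j)
        if md.at[i, "specimen_id"] == md.at[j, "specimen_id"]:
            key = "intra_run" if md.at[i, "run_id"] == md.at[j, "run_id"] else "inter_run"
        else:
            key = "biological"
        sets[key].append(d)
    groups = {k: np.asarray(v, dtype=float) for k, v in sets.items()}
    empty = tuple(k for k, v in groups.items() if v.size == 0)
    return DistanceGroups(groups=groups, empty=empty)
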