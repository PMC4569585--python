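"""Multivariate wave-regime analysis.

Each census year's wave climate is represented by the pairwise Euclidean
distances among stations over the 34-month *recruitment period* (May of the
census year back through the third previous August).  A *second-stage*
analysis then rank-correlates those whole distance matrices across years:
years whose spatial wave-energy structure co-varies get high Spearman rho.
The second-stage matrix (dissimilarity 1 - rho) is ordinated (nMDS),
clustered (UPGMA) and tested for a priori year groupings (ANOSIM); pairs of
second-stage matrices from different observation scales are compared with a
Spearman Mantel test (the RELATE procedure); SIMPER attributes between-group
distance to individual months.

All permutation tests take an explicit seed; small-n results are verified
against brute-force rank computations and scikit-bio in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .waves import RWEField

__all__ = [
    "RecruitmentPeriod",
    "SecondStageMatrix",
    "period_distance_matrix",
    "second_stage",
    "anosim",
    "mantel_relate",
    "nmds",
    "upgma",
    "upgma_newick",
    "simper",
]

PERIOD_MONTHS = 34  # May of census year back through the third previous August


@dataclass(frozen=True)
class RecruitmentPeriod:
    """The 34-month environmental window ending at the May census."""

    census_year: int

    @property
    def months(self) -> pd.PeriodIndex:
        end = pd.Period(f"{self.census_year}-05", freq="M")
        return pd.period_range(end - (PERIOD_MONTHS - 1), end, freq="M")


@dataclass
class SecondStageMatrix:
    """Year x year Spearman correlations of per-year station-distance
    matrices, with derived dissimilarity 1 - rho."""

    rho: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.rho.to_numpy(dtype=float)
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("second-stage matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("second-stage diagonal must be 1")
        if np.nanmax(np.abs(r)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def dissimilarity(self) -> pd.DataFrame:
        d = 1.0 - self.rho
        np.fill_diagonal(d.values, 0.0)
        return d


def _as_square(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    return a


def _lower(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(m, k=-1)
    return m[i, j]


def period_distance_matrix(field: RWEField, period: RecruitmentPeriod) -> pd.DataFrame:
    """Station x station Euclidean distances over the period's monthly RWE vectors."""
    months = period.months
    missing = [m for m in months if m not in field.matrix.columns]
    if missing:
        raise ValueError(f"field does not cover recruitment period months {missing}")
    X = field.matrix[list(months)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [m for m in months if field.matrix[m].isna().any()]
        raise ValueError(f"recruitment period has missing months {bad}; periods must be complete")
    D = squareform(pdist(X))
    return pd.DataFrame(D, index=field.matrix.index, columns=field.matrix.index)


def second_stage(matrices: dict[int, pd.DataFrame]) -> SecondStageMatrix:
    """Spearman rho between the lower triangles of every pair of per-year
    distance matrices (>= 3 years, conformable)."""
    years = sorted(matrices)
    if len(years) < 3:
        raise ValueError("second-stage analysis needs at least 3 years")
    tris = {}
    shape = None
    for y in years:
        m = _as_square(matrices[y])
        if shape is None:
            shape = m.shape
        elif m.shape != shape:
            raise ValueError("per-year distance matrices are not conformable")
        tris[y] = _lower(m)
    n = len(years)
    rho = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            r = spearmanr(tris[years[a]], tris[years[b]]).statistic
            rho[a, b] = rho[b, a] = r
    return SecondStageMatrix(pd.DataFrame(rho, index=years, columns=years))


def anosim(
    dissim, groups, n_perm: int = 999, seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranked pairwise dissimilarities (average ranks on ties).
    P is the fraction of label permutations (seeded) with R* >= R, counting
    the observed labelling.
    """
    D = _as_square(dissim)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members (singleton group found)")
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(D[iu])
    M = n * (n - 1) / 2

    def r_stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    r_obs = r_stat(groups)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 1  # observed labelling counts
    for _ in range(n_perm):
        hits += r_stat(rng.permutation(groups)) >= r_obs - 1e-12
    return float(r_obs), float(hits / (n_perm + 1))


def mantel_relate(
    m1, m2, n_perm: int = 999, seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman rank Mantel test between two conformable symmetric matrices
    (the RELATE procedure).  P by seeded simultaneous row/column permutation
    of the second matrix."""
    a, b = _as_square(m1), _as_square(m2)
    if a.shape != b.shape:
        raise ValueError("matrices are not conformable")
    rho_obs = spearmanr(_lower(a), _lower(b)).statistic
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a.shape[0]
    hits = 1
    for _ in range(n_perm):
        p = rng.permutation(n)
        rho = spearmanr(_lower(a), _lower(b[np.ix_(p, p)])).statistic
        hits += rho >= rho_obs - 1e-12
    return float(rho_obs), float(hits / (n_perm + 1))


def kruskal_stress1(embedding: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against a dissimilarity matrix:
    sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ), dhat = isotonic regression
    of embedded distances on the dissimilarity order."""
    d_emb = pdist(embedding)
    d_in = squareform(_as_square(dissim), checks=False)
    iso = IsotonicRegression()
    dhat = iso.fit_transform(d_in, d_emb)
    denom = float(np.sum(d_emb**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_emb - dhat) ** 2) / denom))


def nmds(
    dissim, dim: int = 2, restarts: int = 100, seed: int = 0, max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS minimizing Kruskal stress-1; best of seeded restarts.

    One restart is initialized from the classical (metric) solution, the
    rest from random configurations; the returned stress is stress-1
    recomputed from the winning embedding.
    """
    D = _as_square(dissim)
    n = D.shape[0]
    if n < dim + 1:
        raise ValueError(f"need at least dim+1 = {dim + 1} objects, got {n}")
    rng = np.random.default_rng(seed)

    # classical scaling init (double-centered eigendecomposition)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    init_cmds = v[:, order] * np.sqrt(np.clip(w[order], 0, None))

    best, best_stress = None, np.inf
    inits = [init_cmds] + [rng.standard_normal((n, dim)) for _ in range(max(restarts - 1, 0))]
    for init in inits:
        emb, _ = smacof(
            D, metric=False, n_components=dim, init=init, n_init=1,
            max_iter=max_iter, eps=1e-9, normalized_stress=False, random_state=0,
        )
        s1 = kruskal_stress1(emb, D)
        if s1 < best_stress:
            best, best_stress = emb, s1
    return best, float(best_stress)


def upgma(dissim) -> np.ndarray:
    """Group-average agglomerative clustering; returns a scipy linkage matrix.

    scipy's average linkage on the condensed matrix is deterministic with
    index-order tie-breaking.
    """
    D = _as_square(dissim)
    return linkage(squareform(D, checks=False), method="average")


def upgma_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string (branch lengths from
    ultrametric merge heights)."""
    tree = to_tree(Z)

    def render(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height / 2:.6g}"
        h = node.dist
        return (
            f"({render(node.left, h)},{render(node.right, h)}):"
            f"{(parent_height - h) / 2:.6g}"
        )

    root = tree
    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


def cut_upgma(Z: np.ndarray, k: int) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster

    return fcluster(Z, t=k, criterion="maxclust")


def simper(profiles: pd.DataFrame, groups) -> pd.DataFrame:
    """Euclidean SIMPER: per-variable contribution to mean between-group
    squared distance.

    ``profiles`` is an object x variable matrix; ``groups`` a 2-level label
    vector.  Each variable's contribution is the mean over between-group
    object pairs of its squared difference; percentages normalize to 100
    (all-zero totals yield zero contributions).
    """
    g = np.asarray(groups)
    labs = np.unique(g)
    if len(labs) != 2:
        raise ValueError("SIMPER here contrasts exactly 2 groups")
    X = profiles.to_numpy(dtype=float)
    ia = np.nonzero(g == labs[0])[0]
    ib = np.nonzero(g == labs[1])[0]
    sq = np.zeros(X.shape[1])
    for i in ia:
        for j in ib:
            sq += (X[i] - X[j]) ** 2
    sq /= len(ia) * len(ib)
    total = sq.sum()
    pct = sq / total * 100.0 if total > 0 else np.zeros_like(sq)
    out = pd.DataFrame({
        "variable": profiles.columns, "mean_sq_contribution": sq, "pct": pct,
    }).sort_values("pct", ascending=False, ignore_index=True)
    out["cum_pct"] = out["pct"].cumsum()
    return out
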