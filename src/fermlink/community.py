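"""Community and flavour stage-structure statistics.

Hellinger distances between samples, principal component / principal
coordinate analysis with a correlation-scaled biplot, Ward hierarchical
clustering with Newick export, permutation AMOVA on distance matrices,
and Spearman correlation of ordination axes with environmental drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sympy.utilities.iterables import multiset_permutations

from fermlink.tables import AbundanceTable


class CommunityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise CommunityError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise CommunityError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise CommunityError("distance matrix diagonal must be zero")
        if arr.min() < -1e-12:
            raise CommunityError("distances must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


def hellinger(abundance: AbundanceTable) -> DistanceMatrix:
    """Hellinger distance between sample compositions.

    d(i, j) = sqrt( sum_k (sqrt(x_ki / s_i) - sqrt(x_kj / s_j))^2 ) where
    s_i is sample i's total.  Bounded by sqrt(2); zero-total samples are
    an error.
    """
    V = abundance.values.to_numpy(dtype=float)
    sums = V.sum(axis=0)
    if (sums == 0).any():
        bad = abundance.samples[sums == 0].tolist()
        raise CommunityError(f"zero-sum sample(s): {bad}")
    roots = np.sqrt(V / sums)          # taxa x samples
    D = squareform(pdist(roots.T, metric="euclidean"))
    return DistanceMatrix(pd.DataFrame(D, index=abundance.samples,
                                       columns=abundance.samples))


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame | None   # features x components (None for PCoA)
    explained: np.ndarray           # R2VX fraction per component
    kind: str = "pca"               # "pca" (feature matrix) or "pcoa" (distances)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None):
    ref = loadings if loadings is not None else scores
    for a in range(scores.shape[1]):
        j = np.argmax(np.abs(ref[:, a]))
        if ref[j, a] < 0:
            scores[:, a] *= -1.0
            if loadings is not None:
                loadings[:, a] *= -1.0
    return scores, loadings


def pca(M: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of a samples x features matrix via SVD of the centered data.

    Loadings are orthonormal; R2VX gives the fraction of total variance
    per component.  The sign convention makes each component's
    largest-magnitude loading positive, so results are reproducible
    across platforms.  Requesting more components than the matrix rank
    truncates with a warning.
    """
    if M.shape[0] < 2:
        raise CommunityError("need at least 2 samples for PCA")
    X = M.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = max(rank, 1)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    scores, loadings = _fix_signs(scores, loadings)
    total = (s ** 2).sum()
    explained = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp_names = [f"PC{a + 1}" for a in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=M.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=M.columns, columns=comp_names),
        explained=explained,
        kind="pca",
    )


def pcoa(D: DistanceMatrix, n_components: int = 2) -> PCAResult:
    """Classical principal coordinates of a distance matrix.

    Double-centers -D^2/2 and eigendecomposes; negative eigenvalues (from
    non-Euclidean distances) are dropped.  Explained fractions are
    relative to the sum of positive eigenvalues.
    """
    A = D.values.to_numpy(dtype=float)
    n = A.shape[0]
    if n < 2:
        raise CommunityError("need at least 2 samples for PCoA")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (A ** 2) @ J
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_components > n_pos:
        warnings.warn(
            f"requested {n_components} axes but only {n_pos} positive "
            f"eigenvalues; truncating", stacklevel=2,
        )
        n_components = max(n_pos, 1)
    scores = evecs[:, :n_components] * np.sqrt(np.maximum(evals[:n_components], 0))
    scores, _ = _fix_signs(scores, None)
    explained = evals[:n_components] / evals[pos].sum()
    comp_names = [f"PCo{a + 1}" for a in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=D.samples, columns=comp_names),
        loadings=None,
        explained=explained,
        kind="pcoa",
    )


def correlation_scaled_biplot(result: PCAResult, M: pd.DataFrame
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation-scaled biplot coordinates over the first two components.

    p(corr)[j, a] is the Pearson correlation between feature j and score
    t_a, so all feature points lie inside the unit circle; t(corr) divides
    both score columns by the largest observation radius, so all
    observations lie inside the unit disk with the extreme one on the rim.
    Constant features get p(corr) = 0 (undefined, flagged).
    """
    if result.scores.shape[1] < 2:
        raise CommunityError("biplot needs at least two components")
    T2 = result.scores.iloc[:, :2].to_numpy()
    X = M.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Tc = T2 - T2.mean(axis=0)
    x_sd = np.sqrt((Xc ** 2).sum(axis=0))
    t_sd = np.sqrt((Tc ** 2).sum(axis=0))
    const = x_sd == 0
    x_sd_safe = np.where(const, 1.0, x_sd)
    p_corr = (Xc.T @ Tc) / np.outer(x_sd_safe, t_sd)
    p_corr[const] = 0.0
    if const.any():
        warnings.warn(
            f"constant feature(s) have undefined correlation loading: "
            f"{M.columns[const].tolist()}", stacklevel=2,
        )
    radii = np.sqrt((T2 ** 2).sum(axis=1))
    r_max = radii.max()
    t_corr = T2 / r_max if r_max > 0 else T2
    cols = list(result.scores.columns[:2])
    return (
        pd.DataFrame(t_corr, index=result.scores.index, columns=cols),
        pd.DataFrame(p_corr, index=M.columns, columns=cols),
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class StagePartition:
    labels: pd.Series                # sample -> group label
    source: str = "metadata"         # "metadata" or "hca_cut"

    def groups(self) -> dict:
        return {g: list(idx) for g, idx in self.labels.groupby(self.labels).groups.items()}


def ward_hca(data: DistanceMatrix | pd.DataFrame) -> np.ndarray:
    """Agglomerative clustering under Ward's minimum-variance criterion.

    Accepts either a precomputed distance matrix or a samples x features
    matrix (Euclidean distances are used).  Returns a scipy linkage
    matrix; merge heights are on the distance scale.
    """
    if isinstance(data, DistanceMatrix):
        if len(data.samples) < 2:
            raise CommunityError("need at least 2 samples")
        cond = data.condensed()
    else:
        if data.shape[0] < 2:
            raise CommunityError("need at least 2 samples")
        cond = pdist(data.to_numpy(dtype=float), metric="euclidean")
    return hierarchy.linkage(cond, method="ward")


def cut_to_groups(linkage_matrix: np.ndarray, k: int, samples) -> StagePartition:
    """Cut a linkage tree into k groups."""
    n = linkage_matrix.shape[0] + 1
    if k > n:
        raise CommunityError(f"cannot cut {n} samples into {k} groups")
    labels = hierarchy.fcluster(linkage_matrix, k, criterion="maxclust")
    return StagePartition(
        labels=pd.Series(labels, index=pd.Index(samples, name="sample")),
        source="hca_cut",
    )


def linkage_to_newick(linkage_matrix: np.ndarray, labels) -> str:
    """Serialize a linkage tree as Newick with merge heights as branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)
    labels = list(labels)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AMOVAResult:
    fs: float
    p_value: float
    n_permutations: int            # 0 for exhaustive enumeration
    exhaustive: bool = False
    pairwise: dict = field(default_factory=dict)


def _amova_fs(D2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def amova(D: DistanceMatrix, partition: StagePartition,
          n_permutations: int | None = 10_000, seed: int = 0,
          pairwise: bool = False) -> AMOVAResult:
    """Permutation analysis of molecular variance on a distance matrix.

    The statistic is Fs = (SS_among / (k-1)) / (SS_within / (n-k)) with
    SS_total = sum_{i<j} d_ij^2 / n and SS_within the analogous per-group
    sums.  The p-value permutes group labels: Monte-Carlo with the +1
    correction p = (1 + #{Fs* >= Fs}) / (1 + B), or, when
    ``n_permutations`` is None, exhaustive enumeration over all distinct
    label arrangements (identity included, no correction).  Groups must
    have at least 2 samples each.
    """
    labels = partition.labels.reindex(D.samples)
    if labels.isna().any():
        raise CommunityError("partition does not cover all samples")
    groups, codes = np.unique(labels.to_numpy(), return_inverse=True)
    k = len(groups)
    if k < 2:
        raise CommunityError("AMOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = groups[sizes < 2].tolist()
        raise CommunityError(f"group(s) with fewer than 2 samples: {small}")
    D2 = D.values.to_numpy(dtype=float) ** 2
    fs_obs = _amova_fs(D2, codes, k)

    if n_permutations is None:
        count = 0
        total = 0
        for perm in multiset_permutations(codes.tolist()):
            total += 1
            if _amova_fs(D2, np.asarray(perm), k) >= fs_obs - 1e-12:
                count += 1
        p = count / total
        result = AMOVAResult(fs=float(fs_obs), p_value=float(p),
                             n_permutations=0, exhaustive=True)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        codes_perm = codes.copy()
        for _ in range(n_permutations):
            rng.shuffle(codes_perm)
            if _amova_fs(D2, codes_perm, k) >= fs_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        result = AMOVAResult(fs=float(fs_obs), p_value=float(p),
                             n_permutations=n_permutations)

    if pairwise:
        for ga, gb in combinations(range(k), 2):
            idx = np.flatnonzero((codes == ga) | (codes == gb))
            sub = DistanceMatrix(D.values.iloc[idx, idx])
            sub_part = StagePartition(labels.iloc[idx], source=partition.source)
            result.pairwise[(str(groups[ga]), str(groups[gb]))] = amova(
                sub, sub_part, n_permutations=n_permutations, seed=seed,
            )
    return result


# ---------------------------------------------------------------------------
# environmental drivers
# ---------------------------------------------------------------------------

def spearman_env(pc1: pd.Series, covariate: pd.Series) -> float:
    """Spearman rank correlation between an ordination axis and a covariate.

    Ties get average ranks.  A constant covariate has no defined rank
    correlation: returns NaN with a warning.
    """
    cov = covariate.reindex(pc1.index)
    if cov.isna().any():
        raise CommunityError("covariate does not cover all samples")
    if len(pc1) < 3:
        raise CommunityError("need at least 3 samples")
    if np.ptp(cov.to_numpy(dtype=float)) == 0:
        warnings.warn("constant covariate: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(pc1.to_numpy(), cov.to_numpy())
    return float(rho)
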