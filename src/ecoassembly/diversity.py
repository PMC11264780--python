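"""Alpha diversity, repeated rarefaction, beta-diversity distances and
distance-based group tests.

Alpha diversity is reported as the Effective Number of Species (ENS), a Hill
number: the count of equally-abundant species that would produce the observed
diversity index.  The default mode is the inverse Simpson concentration
(Hill order 2), which equals the number of species S for a perfectly even
community; ``exp_shannon`` (Hill order 1) and a literal ``exp_simpson_literal``
mode (exp of the Gini-Simpson index, bounded by e) are also available.

Beta diversity: Bray-Curtis on counts or proportions, and weighted UniFrac on
a rooted phylogeny (raw and normalized forms), feeding principal-coordinates
analysis (PCoA), PERMANOVA, and a betadisper-style dispersion-homogeneity
test.  PERMANOVA and the dispersion test are implemented directly so that
exact (exhaustive-permutation) p-values are available for small designs;
both use the p = (1 + #{perm >= obs}) / (1 + n_permutations) convention, so
p >= 1/(n_permutations + 1) always.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core_io import CountTable, MismatchError, Phylogeny, RelativeAbundanceTable

ENS_MODES = ("exp_shannon", "inverse_simpson", "exp_simpson_literal")


@dataclass
class OrdinationResult:
    """Sample coordinates on k PCoA axes with per-axis explained variance."""

    coordinates: pd.DataFrame
    proportion_explained: np.ndarray
    eigvals: np.ndarray
    negative_eigenvalue_mass: float
    degenerate: bool = False


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


# ---------------------------------------------------------------------------
# relative abundance / rarefaction / ENS


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    totals = table.sample_totals().astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    safe = np.where(totals > 0, totals, 1.0)
    props = table.counts / safe
    return RelativeAbundanceTable(
        list(table.taxon_ids), list(table.sample_ids), props, zero_samples=zero
    )


def rarefy(
    table: CountTable, depth: int, n_draws: int, seed: int
) -> tuple[list[CountTable], list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (returned in the
    second element).  Identical seed gives identical draws.
    """
    if depth < 1 or n_draws < 1:
        raise ValueError("depth and n_draws must be >= 1")
    totals = table.sample_totals()
    keep = [s for s, t in zip(table.sample_ids, totals) if t >= depth]
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if not keep:
        raise ValueError(f"rarefaction depth {depth} exceeds every sample total")
    sub = table.select_samples(keep)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        mat = np.empty_like(sub.counts)
        for j in range(sub.n_samples):
            mat[:, j] = rng.multivariate_hypergeometric(sub.counts[:, j], depth)
        draws.append(CountTable(list(sub.taxon_ids), list(sub.sample_ids), mat))
    return draws, dropped


def ens(proportions: np.ndarray, mode: str = "inverse_simpson") -> float:
    """Effective number of species of one relative-abundance vector."""
    if mode not in ENS_MODES:
        raise ValueError(f"unknown ENS mode {mode!r}")
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("all-zero abundance vector has no diversity")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("proportions must sum to 1")
    if mode == "exp_shannon":
        return float(np.exp(-np.sum(p * np.log(p))))
    simpson = float(np.sum(p**2))
    if mode == "inverse_simpson":
        return 1.0 / simpson
    return float(np.exp(1.0 - simpson))  # exp_simpson_literal


def ens_table(
    table: CountTable,
    mode: str = "inverse_simpson",
    depth: int | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample ENS averaged over repeated rarefaction draws.

    ``depth=None`` uses the minimum sample total.  ``depth=0`` disables
    rarefaction and computes ENS on the raw proportions.
    """
    if depth == 0:
        rel = to_relative(table)
        vals = {
            s: ens(rel.proportions[:, j], mode)
            for j, s in enumerate(table.sample_ids)
        }
        used_depth, n_draws_used = None, 0
    else:
        if depth is None:
            depth = int(table.sample_totals().min())
        draws, _ = rarefy(table, depth, n_draws, seed)
        acc: dict[str, list[float]] = {s: [] for s in draws[0].sample_ids}
        for d in draws:
            rel = to_relative(d)
            for j, s in enumerate(d.sample_ids):
                acc[s].append(ens(rel.proportions[:, j], mode))
        vals = {s: float(np.mean(v)) for s, v in acc.items()}
        used_depth, n_draws_used = depth, n_draws
    return pd.DataFrame(
        {
            "sample_id": list(vals),
            "ens": [vals[s] for s in vals],
            "mode": mode,
            "rarefaction_depth": used_depth,
            "n_rarefactions": n_draws_used,
        }
    )


# ---------------------------------------------------------------------------
# distances and ordination


def bray_curtis_matrix(
    table: CountTable | RelativeAbundanceTable,
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y)."""
    mat = (
        table.counts if isinstance(table, CountTable) else table.proportions
    ).astype(float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = mat.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size >= 2:
        pair = (table.sample_ids[zero[0]], table.sample_ids[zero[1]])
        raise ValueError(f"Bray-Curtis undefined for all-zero sample pair {pair}")
    d = squareform(pdist(mat.T, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def weighted_unifrac_matrix(
    table: CountTable, tree: Phylogeny, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac: branch lengths weighted by abundance-proportion flow."""
    missing = set(table.taxon_ids) - set(tree.leaf_names())
    if missing:
        raise MismatchError(f"taxa absent from tree: {sorted(missing)[:10]}")
    return beta_diversity(
        "weighted_unifrac",
        table.counts.T,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree.tree,
        normalized=normalized,
    )


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric scaling of a distance matrix onto ``k`` axes.

    Negative eigenvalues (non-Euclidean input) are reported via
    ``negative_eigenvalue_mass`` and excluded from the explained-variance
    denominator.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    if k > n - 1:
        k = n - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", dimensions=0, warn_neg_eigval=False)
    eig = np.asarray(res.eigvals, dtype=float)
    neg_mass = float(-eig[eig < 0].sum())
    pos = np.clip(eig, 0.0, None)
    total = pos.sum()
    if total <= 0:
        coords = pd.DataFrame(
            np.zeros((n, k)), index=list(d.ids), columns=[f"PC{i+1}" for i in range(k)]
        )
        return OrdinationResult(coords, np.zeros(k), eig, neg_mass, degenerate=True)
    explained = pos / total
    coords = res.samples.iloc[:, :k].copy()
    coords.index = list(d.ids)
    coords.columns = [f"PC{i+1}" for i in range(k)]
    return OrdinationResult(coords, explained[:k], eig, neg_mass)


# ---------------------------------------------------------------------------
# permutation tests


def _ss_within(w2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += w2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss


def _pseudo_f(w2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = len(labels)
    k = len(groups)
    ss_total = w2.sum() / (2 * n)
    ss_within = _ss_within(w2, labels, groups)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    d: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> GroupTestResult:
    """Distance-based one-way PERMANOVA (pseudo-F, free label permutation).

    With ``exhaustive=True`` all n! label orderings are enumerated and the
    p-value is the exact fraction with F >= observed (identity included).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if not exhaustive and n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    w2 = d.data**2
    f_obs = _pseudo_f(w2, labels, groups)
    if exhaustive:
        n_ge = 0
        total = 0
        for perm in itertools.permutations(range(len(labels))):
            total += 1
            if _pseudo_f(w2, labels[list(perm)], groups) >= f_obs - 1e-12:
                n_ge += 1
        return GroupTestResult(f_obs, n_ge / total, total, "permanova")
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        if _pseudo_f(w2, rng.permutation(labels), groups) >= f_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return GroupTestResult(f_obs, p, n_permutations, "permanova")


def _anova_f(values: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = len(values)
    k = len(groups)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        v = values[labels == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def dispersion_test(
    d: DistanceMatrix, labels, n_permutations: int = 999, seed: int = 0
) -> GroupTestResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Each sample's distance to its group centroid is measured in full-rank
    PCoA space (positive-eigenvalue axes); the statistic is the one-way
    ANOVA F on those distances.  Each permutation reassigns samples to
    groups and recomputes the centroid distances, which keeps the test
    exact under exchangeability (permuting fixed distances is liberal,
    because within-group distances share an estimated centroid).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("dispersion test needs at least 2 groups")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", dimensions=0, warn_neg_eigval=False)
    eig = np.asarray(res.eigvals, dtype=float)
    coords = np.asarray(res.samples)[:, eig > 1e-12]
    def centroid_distances(lab: np.ndarray) -> np.ndarray:
        z = np.empty(len(lab))
        for g in groups:
            idx = np.flatnonzero(lab == g)
            centroid = coords[idx].mean(axis=0)
            z[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
        return z

    z_obs = centroid_distances(labels)
    # constant centroid distances (up to float noise) carry no dispersion
    # signal under any labelling
    if np.ptp(z_obs) <= 1e-9 * max(1.0, np.abs(z_obs).max()):
        return GroupTestResult(0.0, 1.0, n_permutations, "betadisper")
    f_obs = _anova_f(z_obs, labels, groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anova_f(centroid_distances(perm), perm, groups) >= f_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return GroupTestResult(f_obs, p, n_permutations, "betadisper")


def rank_sum_test(x, y) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration for small tie-free samples (n1 + n2 <= 20), otherwise
    the tie-corrected normal approximation with midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult(float(res.statistic), float(res.pvalue), 0, "rank_sum")
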