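"""Phylogenetic and taxonomic null models for community assembly.

For every pair of communities the module computes:

* βMNTD — the (abundance-weighted) mean phylogenetic distance from each taxon
  in one community to its nearest relative in the other;
* βNTI — the standardized effect size of βMNTD against a null distribution
  obtained by shuffling taxon identities uniformly across the tips of the
  pool's phylogeny (equivalently, a simultaneous random permutation of the
  rows and columns of the patristic distance matrix);
* RC_bray — the Raup-Crick position of the observed Bray-Curtis dissimilarity
  within a null distribution of dissimilarities between probabilistically
  re-assembled communities (richness drawn proportional to taxon occupancy,
  reads filled multinomially proportional to pool-wide relative abundance,
  at least one read per drawn taxon), rescaled to [-1, 1];

and classifies each pair into one of five assembly processes:

* |βNTI| >= 2          → selection (heterogeneous if βNTI > 0, homogeneous if < 0)
* |βNTI| < 2, RC >= 0.95  → dispersal limitation combined with drift
* |βNTI| < 2, RC <= -0.95 → homogenizing dispersal
* otherwise            → drift alone

Boundary values land in the non-drift category.  Pairs whose null standard
deviation is zero are flagged undefined and excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountTable, Phylogeny, SampleMetadata

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation_drift",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class NullModelConfig:
    n_reps: int = 999
    seed: int = 0
    abundance_weighted: bool = True
    pool_scope: str = "group"  # {"group", "all_samples"}

    def __post_init__(self) -> None:
        if self.n_reps < 99:
            raise ValueError("n_reps must be >= 99")
        if self.pool_scope not in ("group", "all_samples"):
            raise ValueError(f"unknown pool_scope {self.pool_scope!r}")


@dataclass
class ClassificationThresholds:
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class AssemblyResult:
    """Pairwise βMNTD/βNTI/RC_bray table plus per-group process fractions."""

    pairs: pd.DataFrame
    fractions: pd.DataFrame | None = None
    config: NullModelConfig | None = None
    thresholds: ClassificationThresholds | None = None
    n_undefined: int = 0
    assumptions: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# βMNTD / βNTI


def _relative_rows(counts: np.ndarray) -> np.ndarray:
    """Counts (taxa x samples) -> per-sample relative abundances (samples x taxa)."""
    mat = counts.T.astype(float)
    totals = mat.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("empty sample in βMNTD input")
    return mat / totals


def _bmntd_all_pairs(
    freqs: np.ndarray,
    present: list[np.ndarray],
    dmat: np.ndarray,
    abundance_weighted: bool,
) -> np.ndarray:
    """βMNTD for all sample pairs.

    ``freqs``: samples x taxa relative abundances; ``present[m]``: indices of
    taxa present in sample m; ``dmat``: taxa x taxa patristic distances.
    """
    n, n_taxa = freqs.shape
    if not abundance_weighted:
        freqs = np.zeros_like(freqs)
        for m, idx in enumerate(present):
            freqs[m, idx] = 1.0 / idx.size
    dmin = np.empty((n, n_taxa))
    for m, idx in enumerate(present):
        dmin[m] = dmat[:, idx].min(axis=1)
    half = freqs @ dmin.T  # half[k, m] = sum_i f_ki * min_{j in m} d(i, j)
    return 0.5 * (half + half.T)


def beta_mntd(
    rel_or_counts,
    sample_a: str,
    sample_b: str,
    tree: Phylogeny,
    abundance_weighted: bool = True,
) -> float:
    """βMNTD between two samples of a count or relative-abundance table."""
    taxon_ids = rel_or_counts.taxon_ids
    mat = (
        rel_or_counts.counts
        if isinstance(rel_or_counts, CountTable)
        else rel_or_counts.proportions
    )
    ia = rel_or_counts.sample_ids.index(sample_a)
    ib = rel_or_counts.sample_ids.index(sample_b)
    sub = np.asarray(mat, dtype=float)[:, [ia, ib]]
    freqs = _relative_rows(sub)
    present = [np.flatnonzero(sub[:, 0] > 0), np.flatnonzero(sub[:, 1] > 0)]
    dm = tree.prune_to(taxon_ids).patristic_matrix()
    order = [list(dm.ids).index(t) for t in taxon_ids]
    dmat = dm.data[np.ix_(order, order)]
    return float(
        _bmntd_all_pairs(freqs, present, dmat, abundance_weighted)[0, 1]
    )


def _pool_distance_matrix(table: CountTable, tree: Phylogeny) -> np.ndarray:
    dm = tree.prune_to(table.taxon_ids).patristic_matrix()
    order = [list(dm.ids).index(t) for t in table.taxon_ids]
    return dm.data[np.ix_(order, order)]


def bnti_matrix(
    table: CountTable, tree: Phylogeny, config: NullModelConfig
) -> pd.DataFrame:
    """Observed βMNTD, null mean/sd and βNTI for every sample pair.

    The pool is the set of taxa occurring in at least one sample of
    ``table``; each null replicate shuffles taxon identities across the tips
    of the pool's pruned tree.  Deterministic for a fixed config.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    occupied = [t for t, row in zip(table.taxon_ids, table.counts) if row.sum() > 0]
    if len(occupied) < table.n_taxa:
        table = table.select_taxa(occupied)
    dmat = _pool_distance_matrix(table, tree)
    n_taxa = table.n_taxa
    freqs = _relative_rows(table.counts)
    present = [np.flatnonzero(table.counts[:, j] > 0) for j in range(table.n_samples)]

    obs = _bmntd_all_pairs(freqs, present, dmat, config.abundance_weighted)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB17]))
    n = table.n_samples
    nulls = np.empty((config.n_reps, n, n))
    for r in range(config.n_reps):
        perm = rng.permutation(n_taxa)
        nulls[r] = _bmntd_all_pairs(
            freqs, present, dmat[np.ix_(perm, perm)], config.abundance_weighted
        )
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            sd = null_sd[i, j]
            bnti = (obs[i, j] - null_mean[i, j]) / sd if sd > 0 else np.nan
            rows.append(
                {
                    "sample_i": table.sample_ids[i],
                    "sample_j": table.sample_ids[j],
                    "bmntd_obs": obs[i, j],
                    "null_mean": null_mean[i, j],
                    "null_sd": sd,
                    "bnti": bnti,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RC_bray


def _gumbel_topk(
    log_w: np.ndarray, k: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """n_reps weighted samples of k items without replacement (Gumbel top-k)."""
    keys = log_w[None, :] + rng.gumbel(size=(n_reps, log_w.size))
    return np.argpartition(-keys, k - 1, axis=1)[:, :k]


def _null_fill(
    idx: np.ndarray, pool_ab: np.ndarray, total: int, rng: np.random.Generator
) -> np.ndarray:
    """Distribute ``total`` reads over drawn taxa: one guaranteed read each,
    remainder multinomial proportional to pool-wide relative abundance."""
    p = pool_ab[idx]
    p = p / p.sum()
    return rng.multinomial(total - idx.size, p) + 1


def rc_score(obs: float, nulls: np.ndarray) -> float:
    """Raup-Crick rescaling of an observed value against its null sample:
    2 * [(#{null < obs} + 0.5 * #{null = obs}) / n] - 1, ties at 1e-12."""
    nulls = np.asarray(nulls, dtype=float)
    less = int((nulls < obs - 1e-12).sum())
    eq = int(((nulls >= obs - 1e-12) & (nulls <= obs + 1e-12)).sum())
    return 2.0 * ((less + 0.5 * eq) / nulls.size) - 1.0


def rc_bray_matrix(table: CountTable, config: NullModelConfig) -> pd.DataFrame:
    """Raup-Crick standardized Bray-Curtis for every sample pair.

    RC = 2 * [(#{null < obs} + 0.5 * #{null = obs}) / n_reps] - 1, so RC near
    +1 means the pair is more dissimilar than expected under stochastic
    re-assembly from the pool, RC near -1 more similar.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts
    occupancy = (counts > 0).mean(axis=1)
    pool_ab = counts.sum(axis=1).astype(float)
    pool_ab = pool_ab / pool_ab.sum()
    n_pool = int((occupancy > 0).sum())
    if n_pool < 2:
        raise ValueError("pool must contain at least 2 taxa")
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    if richness.max() > n_pool:
        raise ValueError("sample richness exceeds pool taxon count")
    with np.errstate(divide="ignore"):
        log_occ = np.log(occupancy)

    n = table.n_samples
    n_taxa = table.n_taxa
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5C]))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            xi = counts[:, i].astype(float)
            xj = counts[:, j].astype(float)
            obs = np.abs(xi - xj).sum() / (xi + xj).sum()
            idx_i = _gumbel_topk(log_occ, int(richness[i]), config.n_reps, rng)
            idx_j = _gumbel_topk(log_occ, int(richness[j]), config.n_reps, rng)
            nulls = np.empty(config.n_reps)
            u = np.zeros(n_taxa)
            v = np.zeros(n_taxa)
            denom = float(totals[i] + totals[j])
            for r in range(config.n_reps):
                u[:] = 0.0
                v[:] = 0.0
                u[idx_i[r]] = _null_fill(idx_i[r], pool_ab, int(totals[i]), rng)
                v[idx_j[r]] = _null_fill(idx_j[r], pool_ab, int(totals[j]), rng)
                nulls[r] = np.abs(u - v).sum() / denom
            rc = rc_score(obs, nulls)
            rows.append(
                {
                    "sample_i": table.sample_ids[i],
                    "sample_j": table.sample_ids[j],
                    "bc_obs": obs,
                    "rc_bray": rc,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification


def classify_process(
    bnti: float, rc: float, t: ClassificationThresholds | None = None
) -> str:
    """Map a (βNTI, RC_bray) pair to its assembly-process label."""
    t = t or ClassificationThresholds()
    if not (np.isfinite(bnti) and np.isfinite(rc)):
        raise ValueError("βNTI and RC_bray must be finite")
    if bnti >= t.bnti_threshold:
        return "heterogeneous_selection"
    if bnti <= -t.bnti_threshold:
        return "homogeneous_selection"
    if rc >= t.rc_threshold:
        return "dispersal_limitation_drift"
    if rc <= -t.rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def process_fractions(pairs: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group fraction of classified pairs assigned to each process."""
    rows = []
    for group, sub in pairs.groupby(group_col, sort=True):
        classified = sub[sub["process"].notna() & (sub["process"] != "undefined")]
        if classified.empty:
            raise ValueError(f"group {group!r} has no classified pairs")
        counts = classified["process"].value_counts()
        total = int(counts.sum())
        row = {"group": group, "n_pairs": total}
        for proc in PROCESSES:
            row[proc] = counts.get(proc, 0) / total
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-group orchestration


def assembly_analysis(
    table: CountTable,
    tree: Phylogeny,
    meta: SampleMetadata,
    config: NullModelConfig | None = None,
    thresholds: ClassificationThresholds | None = None,
    group_cols: tuple[str, ...] = ("niche", "health"),
) -> AssemblyResult:
    """Full βNTI + RC_bray + classification, pairs formed within groups only.

    ``pool_scope="group"`` restricts both null models' taxon pools to the
    taxa occurring within each group; ``"all_samples"`` uses the whole table
    as the pool while still classifying only within-group pairs.
    """
    config = config or NullModelConfig()
    thresholds = thresholds or ClassificationThresholds()
    labels = meta.group_labels(group_cols)
    frames = []
    skipped = []
    if config.pool_scope == "all_samples":
        sub_bnti = bnti_matrix(table, tree, config)
        sub_rc = rc_bray_matrix(table, config)
        merged_all = sub_bnti.merge(sub_rc, on=["sample_i", "sample_j"])
        lab = dict(labels)
        same = merged_all.apply(
            lambda r: lab[r["sample_i"]] == lab[r["sample_j"]], axis=1
        )
        merged_all = merged_all[same].copy()
        merged_all["group"] = [lab[s] for s in merged_all["sample_i"]]
        frames.append(merged_all)
    else:
        for gi, group in enumerate(sorted(labels.unique())):
            ids = [s for s in table.sample_ids if labels.get(s) == group]
            if len(ids) < 2:
                skipped.append(group)
                continue
            sub = table.select_samples(ids)
            gconf = NullModelConfig(
                n_reps=config.n_reps,
                seed=int(
                    np.random.SeedSequence([config.seed, gi]).generate_state(1)[0]
                    % (2**31)
                ),
                abundance_weighted=config.abundance_weighted,
                pool_scope=config.pool_scope,
            )
            merged = bnti_matrix(sub, tree, gconf).merge(
                rc_bray_matrix(sub, gconf), on=["sample_i", "sample_j"]
            )
            merged["group"] = group
            frames.append(merged)
    if not frames:
        raise ValueError("no group had >= 2 samples")
    pairs = pd.concat(frames, ignore_index=True)
    proc = []
    n_undef = 0
    for _, r in pairs.iterrows():
        if np.isfinite(r["bnti"]) and np.isfinite(r["rc_bray"]):
            proc.append(classify_process(r["bnti"], r["rc_bray"], thresholds))
        else:
            proc.append("undefined")
            n_undef += 1
    pairs["process"] = proc
    fractions = process_fractions(pairs)
    return AssemblyResult(
        pairs=pairs,
        fractions=fractions,
        config=config,
        thresholds=thresholds,
        n_undefined=n_undef,
        assumptions={
            "n_reps": config.n_reps,
            "abundance_weighted": config.abundance_weighted,
            "pool_scope": config.pool_scope,
            "bnti_threshold": thresholds.bnti_threshold,
            "rc_threshold": thresholds.rc_threshold,
            "skipped_groups": skipped,
            "note": "replicate count, pool definition and abundance weighting "
            "are configuration choices; boundary ties classify as non-drift",
        },
    )
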