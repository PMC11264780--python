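"""Core-taxa detection, taxonomic aggregation, chemistry correlations and
Mantel tests linking community structure to geography and soil chemistry.

A taxon is "core" for a sample group when it occurs in at least 95% of the
group's samples AND its mean relative abundance across those samples is at
least 0.1% (both comparisons inclusive).  Phylum-level Spearman correlations
with soil chemistry are Benjamini-Hochberg adjusted within each
niche x health group.  Geographic distances are great-circle (haversine,
Earth radius 6371 km) between farms; chemistry distances are Euclidean on
per-variable z-scores.  Mantel tests correlate the upper triangles of two
distance matrices with a one-sided (greater) permutation p-value, the
convention for distance-decay hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import haversine_distances
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .core_io import (
    CHEMISTRY_VARS,
    CountTable,
    RelativeAbundanceTable,
    SampleMetadata,
    Taxonomy,
    TAXONOMY_RANKS,
)
from .diversity import to_relative

EARTH_RADIUS_KM = 6371.0


@dataclass
class CoreTaxaResult:
    taxa: list[str]
    prevalence_min: float
    abundance_min: float
    n_samples: int


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    n: int


def core_taxa(
    table: CountTable,
    group_samples: list[str],
    prevalence_min: float = 0.95,
    abundance_min: float = 0.001,
) -> CoreTaxaResult:
    """Taxa passing joint prevalence and mean relative-abundance thresholds."""
    if not group_samples:
        raise ValueError("empty sample subset")
    sub = table.select_samples(list(group_samples))
    rel = to_relative(sub)
    prevalence = (sub.counts > 0).mean(axis=1)
    mean_ab = rel.proportions.mean(axis=1)
    # inclusive boundaries, robust to float rounding at exact thresholds
    eps = 1e-12
    core = [
        t
        for t, prev, ab in zip(sub.taxon_ids, prevalence, mean_ab)
        if prev >= prevalence_min - eps and ab >= abundance_min - eps
    ]
    return CoreTaxaResult(core, prevalence_min, abundance_min, len(group_samples))


def venn_partition(
    core_a: set[str] | list[str], core_b: set[str] | list[str]
) -> tuple[set[str], set[str], set[str]]:
    """(only in A, only in B, shared) partition of two core-taxa sets."""
    a, b = set(core_a), set(core_b)
    return a - b, b - a, a & b


def aggregate_to_rank(
    table: CountTable, taxonomy: Taxonomy, rank: str = "phylum"
) -> CountTable:
    """Sum counts of taxa sharing the same lineage value at ``rank``.

    Taxa without a usable lineage at that rank land in an "Unclassified"
    bucket; column totals are conserved exactly.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {rank!r}; known: {list(TAXONOMY_RANKS)}")
    level = TAXONOMY_RANKS.index(rank)
    buckets: dict[str, np.ndarray] = {}
    for i, taxon in enumerate(table.taxon_ids):
        lineage = taxonomy.get(taxon, [])
        name = lineage[level] if len(lineage) > level else "unclassified"
        if not name or name.lower() in ("unclassified", "na", "nan"):
            name = "Unclassified"
        buckets.setdefault(name, np.zeros(table.n_samples, dtype=np.int64))
        buckets[name] += table.counts[i]
    names = sorted(buckets)
    mat = np.vstack([buckets[n] for n in names])
    return CountTable(names, list(table.sample_ids), mat)


def spearman_chemistry(
    rel: RelativeAbundanceTable,
    meta: SampleMetadata,
    group_cols: tuple[str, ...] = ("niche", "health"),
    variables: tuple[str, ...] = CHEMISTRY_VARS,
    min_pairs: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho of each taxon row (e.g. phylum) against each chemistry
    variable, per group, with BH adjustment within each group's test family.

    Incomplete (missing-chemistry) samples are dropped pairwise; rows with a
    constant abundance or chemistry vector are flagged undefined.
    """
    labels = meta.group_labels(group_cols)
    rows = []
    abund = rel.to_dataframe()
    for group in sorted(labels.unique()):
        ids = [s for s in rel.sample_ids if labels.get(s) == group]
        fam: list[dict] = []
        for var in variables:
            chem = meta.frame.loc[ids, var].astype(float)
            for taxon in rel.taxon_ids:
                y = abund.loc[taxon, ids].astype(float)
                ok = chem.notna() & y.notna()
                n = int(ok.sum())
                rec = {
                    "group": group,
                    "taxon": taxon,
                    "variable": var,
                    "n": n,
                }
                if n < min_pairs or chem[ok].nunique() <= 1 or y[ok].nunique() <= 1:
                    rec.update(rho=np.nan, p=np.nan, flag="undefined")
                else:
                    rho, p = stats.spearmanr(y[ok], chem[ok])
                    rec.update(rho=float(rho), p=float(p), flag="ok")
                fam.append(rec)
        valid = [r for r in fam if r["flag"] == "ok"]
        if valid:
            adj = multipletests([r["p"] for r in valid], alpha=alpha, method="fdr_bh")[1]
            for r, pa in zip(valid, adj):
                r["p_adjusted"] = float(pa)
        for r in fam:
            r.setdefault("p_adjusted", np.nan)
        rows.extend(fam)
    return pd.DataFrame(rows)


def ens_chemistry_regression(
    ens_df: pd.DataFrame,
    meta: SampleMetadata,
    group_cols: tuple[str, ...] = ("niche", "health"),
    variables: tuple[str, ...] = CHEMISTRY_VARS,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """OLS of per-sample ENS on each soil-chemistry variable, per group.

    Reports slope, intercept, adjusted R² and the two-sided slope p-value.
    """
    labels = meta.group_labels(group_cols)
    ens_by_sample = ens_df.set_index("sample_id")["ens"]
    rows = []
    for group in sorted(labels.unique()):
        ids = [s for s in ens_by_sample.index if labels.get(s) == group]
        for var in variables:
            chem = meta.frame.loc[ids, var].astype(float)
            y = ens_by_sample.loc[ids]
            ok = chem.notna() & y.notna()
            n = int(ok.sum())
            rec = {"group": group, "variable": var, "n": n}
            if n < min_pairs:
                rec.update(
                    slope=np.nan, intercept=np.nan, adjusted_r2=np.nan,
                    p=np.nan, flag="insufficient",
                )
            elif chem[ok].nunique() <= 1:
                raise ValueError(
                    f"zero predictor variance for {var!r} in group {group!r}"
                )
            else:
                fit = OLS(y[ok].values, add_constant(chem[ok].values)).fit()
                rec.update(
                    slope=float(fit.params[1]),
                    intercept=float(fit.params[0]),
                    adjusted_r2=float(fit.rsquared_adj),
                    p=float(fit.pvalues[1]),
                    flag="ok",
                )
            rows.append(rec)
    return pd.DataFrame(rows)


def geographic_distance_matrix(
    meta: SampleMetadata, level: str = "farm"
) -> DistanceMatrix:
    """Haversine great-circle distances (km) between farms or samples.

    At sample level, farm coordinates are expanded by farm membership, so
    samples of the same farm are at distance 0.
    """
    if level not in ("farm", "sample"):
        raise ValueError(f"unknown level {level!r}")
    if level == "farm":
        farms = meta.farm_table()
        ids = list(farms.index)
        lat = farms["latitude"].to_numpy(dtype=float)
        lon = farms["longitude"].to_numpy(dtype=float)
    else:
        ids = meta.sample_ids
        lat = meta.frame["latitude"].to_numpy(dtype=float)
        lon = meta.frame["longitude"].to_numpy(dtype=float)
    bad = [i for i, (a, b) in enumerate(zip(lat, lon)) if np.isnan(a) or np.isnan(b)]
    if bad:
        raise ValueError(f"missing coordinates for {[ids[i] for i in bad][:5]}")
    rad = np.radians(np.column_stack([lat, lon]))
    d = haversine_distances(rad) * EARTH_RADIUS_KM
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=ids)


def chemistry_distance_matrix(
    meta: SampleMetadata,
    variables: tuple[str, ...] = CHEMISTRY_VARS,
    standardize: bool = True,
    level: str = "farm",
) -> DistanceMatrix:
    """Euclidean distance on (optionally z-scored) chemistry variables."""
    if level == "farm":
        frame = meta.farm_table()[list(variables)]
    else:
        frame = meta.frame[list(variables)]
    ids = list(frame.index)
    x = frame.to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = [ids[i] for i in np.flatnonzero(np.isnan(x).any(axis=1))]
        raise ValueError(f"missing chemistry for {bad[:5]}")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        flat = [v for v, s in zip(variables, sd) if s == 0]
        if flat:
            raise ValueError(f"zero-variance variable(s) under standardize: {flat}")
        x = (x - x.mean(axis=0)) / sd
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=ids)


def expand_to_samples(
    farm_dm: DistanceMatrix, meta: SampleMetadata, sample_ids: list[str]
) -> DistanceMatrix:
    """Expand a farm-level distance matrix to sample pairs by farm membership."""
    farms = meta.frame.loc[sample_ids, "farm_id"]
    idx = [list(farm_dm.ids).index(f) for f in farms]
    d = farm_dm.data[np.ix_(idx, idx)]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=sample_ids)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test between two distance matrices (one-sided, greater)."""
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices have different id sets")
        d2 = d2.filter(d1.ids)
    if d1.shape[0] < 4:
        raise ValueError("Mantel test needs at least 4 units")
    for name, d in (("d1", d1), ("d2", d2)):
        if np.allclose(d.condensed_form(), d.condensed_form()[0]):
            raise ValueError(f"{name} has a constant upper triangle")
    r, p, n = _skbio_mantel(
        d1, d2, method=method, permutations=n_permutations,
        alternative="greater", seed=seed,
    )
    return MantelResult(float(r), float(p), n_permutations, method, int(n))
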