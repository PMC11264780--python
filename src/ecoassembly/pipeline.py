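"""End-to-end orchestration: harmonize -> diversity -> assembly -> associations.

``run_pipeline`` executes the full analysis on a (count table, tree,
metadata, taxonomy) bundle, writing TSV tables plus a JSON manifest that
records every parameter, seed and assumption, so a run is reproducible from
the manifest alone.  All outputs are deterministic functions of the inputs
and the config: repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import (
    AssemblyResult,
    ClassificationThresholds,
    NullModelConfig,
    assembly_analysis,
)
from .associations import (
    chemistry_distance_matrix,
    core_taxa,
    ens_chemistry_regression,
    expand_to_samples,
    geographic_distance_matrix,
    mantel,
    spearman_chemistry,
    venn_partition,
    aggregate_to_rank,
)
from .core_io import (
    CountTable,
    Phylogeny,
    SampleMetadata,
    Taxonomy,
    harmonize,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)
from .diversity import (
    bray_curtis_matrix,
    dispersion_test,
    ens_table,
    pcoa,
    permanova,
    rank_sum_test,
    to_relative,
    weighted_unifrac_matrix,
)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    counts_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    group_cols: tuple[str, ...] = ("niche", "health")
    # null models
    n_reps: int = 999
    abundance_weighted: bool = True
    pool_scope: str = "group"
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    # diversity
    ens_mode: str = "inverse_simpson"
    rarefaction_depth: int | None = None  # None -> per-stratum minimum
    n_rarefactions: int = 100
    n_permutations: int = 999
    # associations
    core_prevalence: float = 0.95
    core_abundance: float = 0.001
    mantel_method: str = "pearson"
    aggregation_rank: str = "phylum"


@dataclass
class RunBundle:
    out_dir: Path
    tables: dict[str, pd.DataFrame]
    manifest: dict
    assembly: AssemblyResult | None = None
    log: list[str] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _load_inputs(
    config: RunConfig,
) -> tuple[CountTable, Phylogeny | None, SampleMetadata, Taxonomy | None]:
    if config.counts_path is None or config.metadata_path is None:
        raise ValueError("config must provide counts_path and metadata_path")
    table = read_count_table(config.counts_path)
    meta = read_metadata(config.metadata_path)
    tree = read_tree(config.tree_path) if config.tree_path else None
    tax = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    return table, tree, meta, tax


def run_pipeline(
    config: RunConfig,
    table: CountTable | None = None,
    tree: Phylogeny | None = None,
    meta: SampleMetadata | None = None,
    taxonomy: Taxonomy | None = None,
) -> RunBundle:
    """Run the full analysis; inputs may be passed in memory or via paths."""
    if table is None:
        table, tree, meta, taxonomy = _load_inputs(config)
    if tree is None:
        raise ValueError(
            "configuration error: assembly and UniFrac analyses require a tree"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    n0_taxa, n0_samples = table.n_taxa, table.n_samples
    table, tree, meta = harmonize(table, tree, meta, policy="intersect")
    log.append(
        f"harmonize: {n0_taxa}->{table.n_taxa} taxa, "
        f"{n0_samples}->{table.n_samples} samples"
    )
    labels = meta.group_labels(config.group_cols)
    niches = sorted(meta.frame["niche"].unique())
    tables: dict[str, pd.DataFrame] = {}

    # ---- diversity -------------------------------------------------------
    ens_frames = []
    beta_rows = []
    ord_frames = []
    for group in sorted(labels.unique()):
        ids = [s for s in table.sample_ids if labels.get(s) == group]
        if len(ids) < 2:
            log.append(f"diversity: stratum {group} skipped (<2 samples)")
            continue
        sub = table.select_samples(ids)
        depth = config.rarefaction_depth
        e = ens_table(
            sub, mode=config.ens_mode, depth=depth,
            n_draws=config.n_rarefactions, seed=config.seed,
        )
        e.insert(1, "group", group)
        ens_frames.append(e)
    ens_all = pd.concat(ens_frames, ignore_index=True)
    tables["ens"] = ens_all

    ens_tests = []
    for niche in niches:
        h = ens_all[ens_all["group"] == f"{niche}/healthy"]["ens"]
        u = ens_all[ens_all["group"] == f"{niche}/unhealthy"]["ens"]
        if len(h) and len(u):
            res = rank_sum_test(h, u)
            ens_tests.append(
                {"niche": niche, "statistic": res.statistic, "p_value": res.p_value,
                 "method": res.method, "n_healthy": len(h), "n_unhealthy": len(u)}
            )
    tables["ens_group_tests"] = pd.DataFrame(ens_tests)

    for niche in niches:
        ids = [s for s in table.sample_ids if meta.frame.loc[s, "niche"] == niche]
        health = meta.frame.loc[ids, "health"]
        if len(ids) < 4 or health.nunique() < 2:
            log.append(f"beta: niche {niche} skipped (too few samples/groups)")
            continue
        sub = table.select_samples(ids)
        dm = weighted_unifrac_matrix(sub, tree, normalized=True)
        ordn = pcoa(dm, k=2)
        coords = ordn.coordinates.copy()
        coords.insert(0, "sample_id", coords.index)
        coords.insert(1, "niche", niche)
        ord_frames.append(coords.reset_index(drop=True))
        perm = permanova(dm, health.values, config.n_permutations, seed=config.seed)
        disp = dispersion_test(dm, health.values, config.n_permutations, seed=config.seed)
        beta_rows.append(
            {"niche": niche, "distance": "weighted_unifrac_normalized",
             "pc1_explained": ordn.proportion_explained[0],
             "pc2_explained": ordn.proportion_explained[1]
             if len(ordn.proportion_explained) > 1 else np.nan,
             "permanova_F": perm.statistic, "permanova_p": perm.p_value,
             "betadisper_F": disp.statistic, "betadisper_p": disp.p_value,
             "n_permutations": config.n_permutations}
        )
    tables["beta_tests"] = pd.DataFrame(beta_rows)
    tables["pcoa_coordinates"] = (
        pd.concat(ord_frames, ignore_index=True) if ord_frames else pd.DataFrame()
    )

    # ---- assembly null models -------------------------------------------
    null_cfg = NullModelConfig(
        n_reps=config.n_reps, seed=config.seed,
        abundance_weighted=config.abundance_weighted, pool_scope=config.pool_scope,
    )
    thresholds = ClassificationThresholds(config.bnti_threshold, config.rc_threshold)
    assembly = assembly_analysis(
        table, tree, meta, null_cfg, thresholds, config.group_cols
    )
    tables["assembly_pairs"] = assembly.pairs
    tables["assembly_fractions"] = assembly.fractions
    if assembly.n_undefined:
        log.append(f"assembly: {assembly.n_undefined} pairs undefined (null sd = 0)")

    # ---- associations ----------------------------------------------------
    core_rows = []
    venn_rows = []
    core_sets: dict[str, set[str]] = {}
    for group in sorted(labels.unique()):
        ids = [s for s in table.sample_ids if labels.get(s) == group]
        if not ids:
            continue
        res = core_taxa(table, ids, config.core_prevalence, config.core_abundance)
        core_sets[group] = set(res.taxa)
        core_rows.append(
            {"group": group, "n_core": len(res.taxa), "n_samples": res.n_samples,
             "prevalence_min": res.prevalence_min, "abundance_min": res.abundance_min,
             "taxa": ";".join(sorted(res.taxa))}
        )
    for niche in niches:
        a = core_sets.get(f"{niche}/healthy")
        b = core_sets.get(f"{niche}/unhealthy")
        if a is None or b is None:
            continue
        only_a, only_b, shared = venn_partition(a, b)
        venn_rows.append(
            {"niche": niche, "only_healthy": len(only_a),
             "only_unhealthy": len(only_b), "shared": len(shared)}
        )
    tables["core_taxa"] = pd.DataFrame(core_rows)
    tables["core_venn"] = pd.DataFrame(venn_rows)

    if taxonomy is not None:
        agg = aggregate_to_rank(table, taxonomy, config.aggregation_rank)
        tables["spearman_chemistry"] = spearman_chemistry(
            to_relative(agg), meta, config.group_cols
        )
    tables["ens_regressions"] = ens_chemistry_regression(
        ens_all, meta, config.group_cols
    )

    mantel_rows = []
    geo_farm = geographic_distance_matrix(meta, level="farm")
    try:
        chem_farm = chemistry_distance_matrix(meta, standardize=True, level="farm")
    except ValueError as exc:
        chem_farm = None
        log.append(f"mantel: chemistry matrix unavailable ({exc})")
    for group in sorted(labels.unique()):
        ids = [s for s in table.sample_ids if labels.get(s) == group]
        if len(ids) < 4:
            log.append(f"mantel: stratum {group} skipped (<4 samples)")
            continue
        d_comm = bray_curtis_matrix(table.select_samples(ids))
        for name, farm_dm in (("geographic", geo_farm), ("chemistry", chem_farm)):
            if farm_dm is None:
                continue
            d_pred = expand_to_samples(farm_dm, meta, ids)
            try:
                res = mantel(
                    d_comm, d_pred, method=config.mantel_method,
                    n_permutations=config.n_permutations, seed=config.seed,
                )
            except ValueError as exc:
                log.append(f"mantel: {group} vs {name} skipped ({exc})")
                continue
            mantel_rows.append(
                {"group": group, "predictor": name, "statistic": res.statistic,
                 "p_value": res.p_value, "method": res.method,
                 "n_permutations": res.n_permutations, "n_samples": res.n}
            )
    tables["mantel"] = pd.DataFrame(mantel_rows)

    # ---- outputs ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "assumptions": assembly.assumptions,
        "log": log,
        "n_taxa": table.n_taxa,
        "n_samples": table.n_samples,
        "outputs": sorted(tables),
    }
    for name, df in tables.items():
        _write_tsv(df, out_dir / f"{name}.tsv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunBundle(out_dir, tables, manifest, assembly, log)
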