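"""Core taxa, phylum-chemistry correlations, diversity regressions, Mantel tests.

Per niche x health group: core taxa (>= 95% prevalence, >= 0.1% mean relative
abundance) with healthy/unhealthy set partitions per niche; Spearman
correlations of phylum-level relative abundance with bulk-soil chemistry
(BH-adjusted); OLS regressions of ENS on each chemistry variable; and Mantel
tests of community Bray-Curtis dissimilarity against farm geographic and
chemistry distances.  Writes five tables under results/associations/.

Usage: python analysis/04_associations.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

import ecoassembly as ea
from ecoassembly.associations import (
    chemistry_distance_matrix,
    core_taxa,
    ens_chemistry_regression,
    expand_to_samples,
    geographic_distance_matrix,
    mantel,
    spearman_chemistry,
    venn_partition,
)
from ecoassembly.core_io import (
    harmonize,
    read_count_table,
    read_metadata,
    read_taxonomy,
)
from ecoassembly.diversity import bray_curtis_matrix, ens_table, to_relative


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--data", type=Path, default=Path("data/synthetic_study"))
    parser.add_argument("--out", type=Path, default=Path("results/associations"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_count_table(args.data / "counts.tsv")
    meta = read_metadata(args.data / "metadata.tsv")
    taxonomy = read_taxonomy(args.data / "taxonomy.tsv")
    table, _, meta = harmonize(table, None, meta)
    labels = meta.group_labels()

    core_rows, core_sets = [], {}
    for group in sorted(labels.unique()):
        ids = [s for s in table.sample_ids if labels.get(s) == group]
        res = core_taxa(table, ids)
        core_sets[group] = set(res.taxa)
        core_rows.append({"group": group, "n_core": len(res.taxa),
                          "taxa": ";".join(sorted(res.taxa))})
    venn_rows = []
    for niche in sorted(meta.frame["niche"].unique()):
        a = core_sets.get(f"{niche}/healthy", set())
        b = core_sets.get(f"{niche}/unhealthy", set())
        only_a, only_b, shared = venn_partition(a, b)
        venn_rows.append({"niche": niche, "only_healthy": len(only_a),
                          "only_unhealthy": len(only_b), "shared": len(shared)})
    pd.DataFrame(core_rows).to_csv(args.out / "core_taxa.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(venn_rows).to_csv(args.out / "core_venn.tsv", sep="\t",
                                   index=False)

    phylum = ea.aggregate_to_rank(table, taxonomy, "phylum")
    corr = spearman_chemistry(to_relative(phylum), meta)
    corr.to_csv(args.out / "spearman_chemistry.tsv", sep="\t", index=False,
                float_format="%.6g")

    frames = []
    for group in sorted(labels.unique()):
        ids = [s for s in table.sample_ids if labels.get(s) == group]
        e = ens_table(table.select_samples(ids), n_draws=50, seed=args.seed)
        e.insert(1, "group", group)
        frames.append(e)
    ens_all = pd.concat(frames, ignore_index=True)
    reg = ens_chemistry_regression(ens_all, meta)
    reg.to_csv(args.out / "ens_regressions.tsv", sep="\t", index=False,
               float_format="%.6g")

    geo = geographic_distance_matrix(meta)
    chem = chemistry_distance_matrix(meta)
    mantel_rows = []
    for group in sorted(labels.unique()):
        ids = [s for s in table.sample_ids if labels.get(s) == group]
        d_comm = bray_curtis_matrix(table.select_samples(ids))
        for name, farm_dm in (("geographic", geo), ("chemistry", chem)):
            try:
                res = mantel(d_comm, expand_to_samples(farm_dm, meta, ids),
                             n_permutations=999, seed=args.seed)
            except ValueError:
                continue
            mantel_rows.append({"group": group, "predictor": name,
                                "statistic": res.statistic,
                                "p_value": res.p_value})
    mant = pd.DataFrame(mantel_rows)
    mant.to_csv(args.out / "mantel.tsv", sep="\t", index=False,
                float_format="%.6g")

    sig = corr[(corr["flag"] == "ok") & (corr["p_adjusted"] <= 0.05)]
    print(f"core taxa per group: "
          f"{ {r['group']: r['n_core'] for r in core_rows} }")
    print(f"{len(sig)} significant phylum-chemistry correlations "
          f"(BH <= 0.05) across groups")
    strongest = reg[reg["flag"] == "ok"].nlargest(3, "adjusted_r2")
    for _, r in strongest.iterrows():
        print(f"  ENS ~ {r['variable']:15s} in {r['group']:28s} "
              f"adj R2 = {r['adjusted_r2']:.3f} (p = {r['p']:.3g})")
    geo_sig = mant[(mant["predictor"] == "geographic") & (mant["p_value"] <= 0.05)]
    print(f"geographic Mantel significant in {len(geo_sig)} of "
          f"{(mant['predictor'] == 'geographic').sum()} groups")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
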