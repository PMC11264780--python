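"""Core taxa, rank aggregation, chemistry correlations and Mantel tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

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
from ecoassembly.core_io import CountTable, SampleMetadata


def _meta(rows):
    return SampleMetadata(pd.DataFrame(rows))


def _sample_row(sid, farm="F1", niche="bulk_soil", health="healthy",
                lat=50.0, lon=23.0, **chem):
    base = {"pH": 6.5, "P2O5": 10.0, "Mg": 12.0, "K2O": 15.0, "organic_carbon": 2.0}
    base.update(chem)
    return {"sample_id": sid, "farm_id": farm, "niche": niche, "health": health,
            "latitude": lat, "longitude": lon, **base}


class TestCoreTaxa:
    def _table(self, prevalence_hits, n_samples, per_sample, total):
        """One focal taxon at ``per_sample`` reads in ``prevalence_hits``
        samples; every sample holds ``total`` reads via a dominant filler."""
        focal = np.zeros(n_samples, dtype=int)
        focal[:prevalence_hits] = per_sample
        rest = np.full(n_samples, total) - focal
        return CountTable(
            ["focal", "rest"], [f"s{i}" for i in range(n_samples)],
            np.vstack([focal, rest]),
        )

    def test_ubiquitous_abundant_taxon_is_core(self):
        t = self._table(20, 20, 20, 2000)  # 1% everywhere
        res = core_taxa(t, t.sample_ids)
        assert "focal" in res.taxa

    def test_exact_boundary_is_core(self):
        # 19/20 samples = 0.95 prevalence; 2/1900 reads in each of the 19
        # samples puts the mean relative abundance exactly at 0.1%
        t = self._table(19, 20, 2, 1900)
        res = core_taxa(t, t.sample_ids)
        prev = (t.counts[0] > 0).mean()
        mean_ab = (t.counts[0] / t.sample_totals()).mean()
        assert prev == pytest.approx(0.95)
        assert mean_ab == pytest.approx(0.001, rel=1e-12)
        assert "focal" in res.taxa

    def test_prevalent_but_rare_taxon_not_core(self):
        t = self._table(20, 20, 1, 10_000)  # 0.01% everywhere
        assert "focal" not in core_taxa(t, t.sample_ids).taxa

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 50, size=(30, 15))
        t = CountTable(
            [f"t{i}" for i in range(30)], [f"s{j}" for j in range(15)], counts
        )
        base = set(core_taxa(t, t.sample_ids, 0.5, 0.001).taxa)
        for prev, ab in [(0.6, 0.001), (0.5, 0.01), (0.9, 0.05)]:
            tighter = set(core_taxa(t, t.sample_ids, prev, ab).taxa)
            assert tighter <= base

    def test_empty_subset_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            core_taxa(tiny_table, [])


class TestVennPartition:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y", "z"}, {"y", "z", "w"}, ({"x"}, {"w"}, {"y", "z"})),
            ({"x"}, {"x"}, (set(), set(), {"x"})),
            ({"x"}, {"y"}, ({"x"}, {"y"}, set())),
        ],
    )
    def test_partitions(self, a, b, expected):
        only_a, only_b, shared = venn_partition(a, b)
        assert (only_a, only_b, shared) == expected
        assert len(only_a) + len(shared) == len(a)


class TestAggregateToRank:
    def test_totals_conserved_and_same_phylum_summed(self, small_dataset):
        ds = small_dataset
        agg = ea.aggregate_to_rank(ds.table, ds.taxonomy, "phylum")
        assert np.array_equal(agg.sample_totals(), ds.table.sample_totals())
        assert agg.n_taxa < ds.table.n_taxa

    def test_two_asvs_of_same_phylum(self):
        t = CountTable(["a1", "a2"], ["s"], np.array([[3], [4]]))
        tax = {"a1": ["Bacteria", "P1"], "a2": ["Bacteria", "P1"]}
        agg = ea.aggregate_to_rank(t, tax, "phylum")
        assert agg.taxon_ids == ["P1"]
        assert agg.counts.tolist() == [[7]]

    def test_missing_lineage_goes_to_unclassified(self):
        t = CountTable(["a1", "a2"], ["s"], np.array([[3], [4]]))
        agg = ea.aggregate_to_rank(t, {"a1": ["Bacteria", "P1"]}, "phylum")
        assert "Unclassified" in agg.taxon_ids

    def test_unknown_rank_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            ea.aggregate_to_rank(small_dataset.table, small_dataset.taxonomy, "color")


class TestSpearmanChemistry:
    def _setup(self, y_values, chem_values):
        n = len(y_values)
        counts = np.vstack([
            np.asarray(y_values, dtype=int),
            np.full(n, 1000) - np.asarray(y_values, dtype=int),
        ])
        t = CountTable(["phylumA", "phylumB"], [f"s{i}" for i in range(n)], counts)
        meta = _meta([
            _sample_row(f"s{i}", pH=chem_values[i]) for i in range(n)
        ])
        return ea.to_relative(t), meta

    def test_perfect_monotone_gives_rho_one(self):
        rel, meta = self._setup([10, 20, 30, 40, 50], [5.0, 5.5, 6.0, 6.5, 7.0])
        out = spearman_chemistry(rel, meta, variables=("pH",))
        row = out[(out["taxon"] == "phylumA") & (out["variable"] == "pH")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_matches_brute_force_rank_oracle(self):
        y = np.array([10, 20, 30, 40, 35])
        chem = np.array([5.0, 6.0, 7.0, 8.0, 7.5])
        rel, meta = self._setup(y, chem)
        out = spearman_chemistry(rel, meta, variables=("pH",))
        row = out[(out["taxon"] == "phylumA") & (out["variable"] == "pH")].iloc[0]
        # independent oracle: Pearson correlation of midranks
        yr = stats.rankdata(y / 1000)
        cr = stats.rankdata(chem)
        want = np.corrcoef(yr, cr)[0, 1]
        assert row["rho"] == pytest.approx(want)

    def test_adjusted_p_at_least_raw_and_bh_monotone(self):
        rng = np.random.default_rng(2)
        n = 12
        counts = rng.integers(1, 100, size=(6, n))
        t = CountTable([f"p{i}" for i in range(6)], [f"s{i}" for i in range(n)], counts)
        meta = _meta([
            _sample_row(f"s{i}", pH=float(rng.normal(6.5, 0.5)),
                        Mg=float(rng.normal(12, 2))) for i in range(n)
        ])
        out = spearman_chemistry(ea.to_relative(t), meta, variables=("pH", "Mg"))
        ok = out[out["flag"] == "ok"].sort_values("p")
        assert (ok["p_adjusted"] >= ok["p"] - 1e-12).all()
        assert ok["p_adjusted"].is_monotonic_increasing

    def test_constant_vector_flagged(self):
        rel, meta = self._setup([10, 10, 10, 10, 10], [5.0, 5.5, 6.0, 6.5, 7.0])
        out = spearman_chemistry(rel, meta, variables=("pH",))
        row = out[(out["taxon"] == "phylumA") & (out["variable"] == "pH")].iloc[0]
        assert row["flag"] == "undefined"


class TestEnsRegression:
    def _ens_df(self, ids, values):
        return pd.DataFrame({"sample_id": ids, "ens": values})

    def test_exact_linear_relationship(self):
        chem = [5.0, 5.5, 6.0, 6.5, 7.0, 7.5]
        meta = _meta([_sample_row(f"s{i}", pH=chem[i]) for i in range(6)])
        ens_df = self._ens_df([f"s{i}" for i in range(6)], [2 * c + 1 for c in chem])
        out = ens_chemistry_regression(ens_df, meta, variables=("pH",))
        row = out.iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["adjusted_r2"] == pytest.approx(1.0)
        assert row["p"] < 1e-8

    def test_duplicated_rows_same_slope_smaller_p(self):
        rng = np.random.default_rng(0)
        chem = list(rng.normal(6.5, 0.5, 8))
        y = [2 * c + rng.normal(0, 0.5) for c in chem]
        meta1 = _meta([_sample_row(f"s{i}", pH=chem[i]) for i in range(8)])
        out1 = ens_chemistry_regression(
            self._ens_df([f"s{i}" for i in range(8)], y), meta1, variables=("pH",)
        ).iloc[0]
        meta2 = _meta([
            _sample_row(f"s{i}", pH=chem[i % 8]) for i in range(16)
        ])
        out2 = ens_chemistry_regression(
            self._ens_df([f"s{i}" for i in range(16)], y + y),
            meta2, variables=("pH",),
        ).iloc[0]
        assert out2["slope"] == pytest.approx(out1["slope"])
        assert out2["p"] < out1["p"]

    def test_zero_variance_predictor_rejected(self):
        meta = _meta([_sample_row(f"s{i}", pH=6.5) for i in range(6)])
        ens_df = self._ens_df([f"s{i}" for i in range(6)], list(range(6)))
        with pytest.raises(ValueError, match="pH"):
            ens_chemistry_regression(ens_df, meta, variables=("pH",))


class TestDistanceMatrices:
    def test_identical_coordinates_zero(self):
        meta = _meta([
            _sample_row("s1", farm="F1"), _sample_row("s2", farm="F2"),
        ])
        d = geographic_distance_matrix(meta)
        assert d["F1", "F2"] == pytest.approx(0.0)

    def test_one_degree_latitude(self):
        meta = _meta([
            _sample_row("s1", farm="F1", lat=50.0, lon=23.0),
            _sample_row("s2", farm="F2", lat=51.0, lon=23.0),
        ])
        d = geographic_distance_matrix(meta)
        assert d["F1", "F2"] == pytest.approx(111.19, abs=0.01)

    def test_metric_properties_on_random_coordinates(self):
        rng = np.random.default_rng(1)
        meta = _meta([
            _sample_row(f"s{i}", farm=f"F{i}",
                        lat=float(rng.uniform(40, 60)),
                        lon=float(rng.uniform(10, 30)))
            for i in range(6)
        ])
        d = geographic_distance_matrix(meta).data
        assert np.allclose(d, d.T)
        for i in range(6):
            for j in range(6):
                assert np.all(d[i, j] <= d[i, :] + d[:, j] + 1e-9)

    def test_missing_coordinate_rejected(self):
        meta = _meta([
            _sample_row("s1", farm="F1"),
            _sample_row("s2", farm="F2", lat=np.nan),
        ])
        with pytest.raises(ValueError, match="F2"):
            geographic_distance_matrix(meta)

    def test_chemistry_identical_rows_zero(self):
        meta = _meta([_sample_row("s1", farm="F1"), _sample_row("s2", farm="F2")])
        with pytest.raises(ValueError):  # all variables constant across farms
            chemistry_distance_matrix(meta)
        d = chemistry_distance_matrix(meta, standardize=False)
        assert d["F1", "F2"] == pytest.approx(0.0)

    def test_chemistry_single_variable_unstandardized(self):
        meta = _meta([
            _sample_row("s1", farm="F1", pH=1.0),
            _sample_row("s2", farm="F2", pH=3.0),
        ])
        d = chemistry_distance_matrix(meta, variables=("pH",), standardize=False)
        assert d["F1", "F2"] == pytest.approx(2.0)

    def test_chemistry_standardized_matches_hand_zscores(self):
        meta = _meta([
            _sample_row(f"s{i}", farm=f"F{i}", pH=v, Mg=m)
            for i, (v, m) in enumerate([(6.0, 10.0), (7.0, 14.0), (6.5, 12.0)])
        ])
        d = chemistry_distance_matrix(meta, variables=("pH", "Mg"))
        ph = np.array([6.0, 7.0, 6.5])
        mg = np.array([10.0, 14.0, 12.0])
        z = np.column_stack([
            (ph - ph.mean()) / ph.std(ddof=1), (mg - mg.mean()) / mg.std(ddof=1)
        ])
        want = np.linalg.norm(z[0] - z[1])
        assert d["F0", "F1"] == pytest.approx(want)


class TestMantel:
    def _random_dm(self, n, seed):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix

        rng = np.random.default_rng(seed)
        return DistanceMatrix(
            squareform(pdist(rng.normal(size=(n, 3)))),
            ids=[f"u{i}" for i in range(n)],
        )

    def test_self_correlation_is_one(self):
        d = self._random_dm(8, 0)
        res = mantel(d, d, n_permutations=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        from skbio.stats.distance import DistanceMatrix

        d = self._random_dm(8, 2)
        d2 = DistanceMatrix(d.data**2, ids=d.ids)
        res = mantel(d, d2, method="spearman", n_permutations=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_invariant_to_joint_reordering(self):
        d1 = self._random_dm(8, 3)
        d2 = self._random_dm(8, 4)
        r1 = mantel(d1, d2, n_permutations=99, seed=9).statistic
        order = list(reversed(list(d1.ids)))
        r2 = mantel(d1.filter(order), d2.filter(order),
                    n_permutations=99, seed=9).statistic
        assert r1 == pytest.approx(r2)

    def test_id_mismatch_rejected(self):
        from skbio.stats.distance import DistanceMatrix

        d1 = self._random_dm(5, 5)
        d2 = DistanceMatrix(d1.data, ids=[f"w{i}" for i in range(5)])
        with pytest.raises(ValueError):
            mantel(d1, d2)

    def test_constant_matrix_rejected(self):
        from skbio.stats.distance import DistanceMatrix

        d1 = self._random_dm(5, 6)
        d2 = DistanceMatrix(1 - np.eye(5), ids=d1.ids)
        with pytest.raises(ValueError, match="constant"):
            mantel(d1, d2)

    def test_expand_to_samples_by_farm(self):
        meta = _meta([
            _sample_row("s1", farm="F1", lat=50.0),
            _sample_row("s2", farm="F1", lat=50.0),
            _sample_row("s3", farm="F2", lat=51.0),
        ])
        farm_dm = geographic_distance_matrix(meta)
        d = expand_to_samples(farm_dm, meta, ["s1", "s2", "s3"])
        assert d["s1", "s2"] == 0.0
        assert d["s1", "s3"] == pytest.approx(farm_dm["F1", "F2"])
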