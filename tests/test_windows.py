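"""Window table construction (exonic-only counting), stratified enrichment,
GC normalization, partial correlation and gene-level analyses."""

import numpy as np
import pandas as pd
import pytest

from g4snv.intervals import GenomicInterval, IntervalSet
from g4snv.sequences import SequenceRecord
from g4snv.windows import (
    count_features,
    gc_normalized_counts,
    gene_class_comparison,
    gene_exon_analysis,
    partial_correlation,
    stratify_enrichment,
)


def snv_frame(positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "patient_id": "p", "cancer_type": "t", "tissue": "x"}
    )


class TestCountFeatures:
    def test_feature_outside_exons_not_counted(self):
        windows = IntervalSet([GenomicInterval("chr1", 0, 5000, label="gene_0")])
        exons = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        g4s = IntervalSet([GenomicInterval("chr1", 2000, 2030)])  # intronic
        tbl = count_features(windows, g4s, snv_frame([500]), snv_frame([1500]), exons)
        assert tbl.loc[0, "g4_count"] == 0
        assert tbl.loc[0, "csnv_count"] == 1  # inside exon
        assert tbl.loc[0, "dbsnv_count"] == 0  # intronic SNV

    def test_empty_window_row_retained(self):
        windows = IntervalSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200)]
        )
        exons = IntervalSet([GenomicInterval("chr1", 0, 200)])
        tbl = count_features(windows, IntervalSet(), None, None, exons)
        assert len(tbl) == 2
        assert (tbl[["g4_count", "csnv_count", "dbsnv_count"]] == 0).all().all()

    def test_gc_and_gene_class_annotation(self):
        genome = {"chr1": SequenceRecord("chr1", "GC" * 50 + "AT" * 50)}
        windows = IntervalSet([GenomicInterval("chr1", 0, 200, label="gene_7")])
        exons = IntervalSet([GenomicInterval("chr1", 0, 200)])
        tbl = count_features(
            windows, IntervalSet(), None, None, exons, genome, {"gene_7": "cancer"}
        )
        assert tbl.loc[0, "gc_bp"] == 100
        assert tbl.loc[0, "gene_class"] == "cancer"

    def test_window_outside_genome_raises(self):
        genome = {"chr1": SequenceRecord("chr1", "ACGT" * 10)}
        windows = IntervalSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="outside"):
            count_features(windows, IntervalSet(), None, None, IntervalSet(), genome)

    def test_matches_nested_loop_oracle_on_random_instances(self, rng):
        for _ in range(50):
            def rand(k, max_len):
                out = []
                for _ in range(k):
                    s = int(rng.integers(0, 3000))
                    out.append(GenomicInterval("chr1", s, s + int(rng.integers(1, max_len))))
                return IntervalSet(out)

            windows = rand(15, 400)
            exons = rand(8, 600)
            g4s = rand(25, 30)
            pos = rng.integers(0, 3500, size=40)
            tbl = count_features(windows, g4s, snv_frame(pos), None, exons)

            def overlaps_exonic(feature, window):
                for e in exons:
                    lo = max(window.start, e.start)
                    hi = min(window.end, e.end)
                    if lo < hi and feature.start < hi and lo < feature.end:
                        return True
                return False

            for wi, w in enumerate(windows):
                exp_g4 = sum(overlaps_exonic(g, w) for g in g4s)
                exp_snv = sum(
                    overlaps_exonic(GenomicInterval("chr1", int(p), int(p) + 1), w)
                    for p in pos
                )
                assert tbl.loc[wi, "g4_count"] == exp_g4
                assert tbl.loc[wi, "csnv_count"] == exp_snv


class TestStratifyEnrichment:
    def make_table(self, pairs):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(pairs)) * 5000,
                "end": (np.arange(len(pairs)) + 1) * 5000,
                "g4_count": [g for g, _ in pairs],
                "csnv_count": [c for _, c in pairs],
                "dbsnv_count": 0,
                "gc_bp": 2000,
                "gene_class": "none",
            }
        )

    def test_closed_form_group_means_and_t_sign(self):
        tbl = self.make_table([(0, 0), (0, 0), (0, 2), (1, 3), (2, 5), (11, 10)])
        res = {r.group: r for r in stratify_enrichment(tbl, "cSNV")}
        assert res["0"].mean == pytest.approx(2 / 3)
        assert res["1+"].mean == pytest.approx(6.0)
        assert res["1+"].statistic < 0  # zero-G4 group has fewer SNVs

    def test_identical_distributions_t_near_zero(self, rng):
        vals = rng.poisson(5, size=400)
        pairs = [(0, v) for v in vals[:200]] + [(1, v) for v in vals[200:]]
        res = {r.group: r for r in stratify_enrichment(self.make_table(pairs), "cSNV")}
        assert abs(res["1+"].statistic) < 2.5
        assert res["1+"].p_value > 0.01

    def test_planted_slope_orders_group_means(self, small_dataset):
        from g4snv.windows import count_features as cf
        from g4snv.intervals import make_windows
        ds = small_dataset
        windows = make_windows(ds.genes, 5000)
        tbl = cf(windows, ds.g4s, ds.csnvs, ds.dbsnvs, ds.exons)
        res = {r.group: r for r in stratify_enrichment(tbl, "cSNV")}
        if "10+" in res:
            assert res["10+"].mean > res["1+"].mean > res["0"].mean
        else:
            assert res["1+"].mean > res["0"].mean

    def test_per_count_weighted_means_consistent_with_overall(self, rng):
        pairs = [(int(g), int(c)) for g, c in zip(rng.integers(0, 4, 300), rng.poisson(4, 300))]
        tbl = self.make_table(pairs)
        per = stratify_enrichment(tbl, "cSNV", grouping="per_count")
        weighted = sum(r.mean * r.n_windows for r in per) / sum(r.n_windows for r in per)
        assert weighted == pytest.approx(tbl["csnv_count"].mean())

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            stratify_enrichment(self.make_table([]), "cSNV")


class TestGcNormalization:
    def test_rate_and_zero_gc_flagging(self):
        tbl = pd.DataFrame(
            {"g4_count": [4, 2, 1], "gc_bp": [2000, 0, 1000]}
        )
        out = gc_normalized_counts(tbl)
        assert out.loc[0, "g4_per_gc"] == pytest.approx(0.002)
        assert np.isnan(out.loc[1, "g4_per_gc"]) and out.loc[1, "gc_flagged"]
        # doubling gc halves the rate
        assert out.loc[0, "g4_per_gc"] == pytest.approx(out.loc[2, "g4_per_gc"] * 2)


class TestPartialCorrelation:
    def test_reduces_to_pearson_when_z_uncorrelated(self, rng):
        n = 5000
        z = np.tile([1.0, -1.0], n // 2)
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        pc = partial_correlation(x, y, z + rng.normal(scale=1e-6, size=n))
        assert pc.r_xy_given_z == pytest.approx(pc.r_xy, abs=0.02)

    def test_known_partial_correlation_recovered(self, rng):
        rho, n = 0.15, 100_000
        z = rng.normal(size=n)
        e = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        pc = partial_correlation(0.5 * z + e[:, 0], 0.5 * z + e[:, 1], z)
        assert abs(pc.r_xy_given_z - rho) < 0.01

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        z = rng.normal(size=1500)
        x = 0.5 * z + rng.normal(size=1500)
        y = 0.4 * z + 0.2 * x + rng.normal(size=1500)
        pc = partial_correlation(x, y, z)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert pc.r_xy_given_z == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert pc.p_value == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_control_variable_explains_y_entirely(self, rng):
        z = rng.normal(size=2000)
        x = rng.normal(size=2000)
        pc = partial_correlation(x, z + rng.normal(scale=1e-3, size=2000), z)
        assert abs(pc.r_xy_given_z) < 0.05

    def test_collinear_control_raises(self, rng):
        z = rng.normal(size=100)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(rng.normal(size=100), z.copy(), z)


class TestGeneLevel:
    def test_per_bp_normalization(self):
        exons = IntervalSet([GenomicInterval("chr1", 0, 500, label="e1"),
                             GenomicInterval("chr1", 1000, 1500, label="e2"),
                             GenomicInterval("chr1", 2000, 2500, label="e3")])
        tbl, r = gene_exon_analysis(exons, IntervalSet(), snv_frame(list(range(10))))
        assert tbl.loc[0, "csnv_per_bp"] == pytest.approx(10 / 500)
        assert tbl.loc[1, "csnv_count"] == 0

    def test_snvs_concentrated_in_g4_exons_give_high_r(self, rng):
        exons = IntervalSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 500, label=f"e{i}") for i in range(8)]
        )
        g4s = IntervalSet([GenomicInterval("chr1", 100, 130), GenomicInterval("chr1", 4100, 4130)])
        pos = list(rng.integers(0, 500, 40)) + list(rng.integers(4000, 4500, 40))
        tbl, r = gene_exon_analysis(exons, g4s, snv_frame([int(p) for p in pos]))
        assert r is not None and r > 0.9

    def test_fewer_than_three_exons_no_correlation(self):
        exons = IntervalSet([GenomicInterval("chr1", 0, 100, label="e")])
        tbl, r = gene_exon_analysis(exons, IntervalSet(), snv_frame([5]))
        assert r is None and len(tbl) == 1


class TestGeneClassComparison:
    def make_table(self, rng, mean_by_class):
        rows = []
        for cls, (mean0, mean10) in mean_by_class.items():
            for _ in range(150):
                rows.append({"g4_count": 0, "csnv_count": rng.poisson(mean0),
                             "dbsnv_count": 0, "gene_class": cls})
                rows.append({"g4_count": 12, "csnv_count": rng.poisson(mean10),
                             "dbsnv_count": 0, "gene_class": cls})
        return pd.DataFrame(rows)

    def test_identical_classes_show_no_between_class_difference(self, rng):
        tbl = self.make_table(rng, {"cancer": (3, 20), "non-cancer": (3, 20)})
        out = gene_class_comparison(tbl, "cSNV")
        a = out["classes"]["cancer"]
        b = out["classes"]["non-cancer"]
        assert a["stratum_10+"]["mean"] == pytest.approx(b["stratum_10+"]["mean"], rel=0.15)
        assert a["welch_t"]["p_value"] < 0.001  # strata differ within class

    def test_single_class_summaries_only(self, rng):
        tbl = self.make_table(rng, {"cancer": (3, 20)})
        out = gene_class_comparison(tbl, "cSNV")
        assert list(out["classes"]) == ["cancer"]

    def test_gene_g4_content_summaries(self, rng):
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(6)],
                "gene_class": ["cancer"] * 3 + ["non-cancer"] * 3,
                "g4_count": [30, 24, 27, 6, 5, 7],
                "length_bp": [2000] * 6,
            }
        )
        tbl = self.make_table(rng, {"cancer": (3, 20)})
        out = gene_class_comparison(tbl, "cSNV", genes=genes)
        assert out["gene_g4_content"]["cancer"]["median"] == 27
        assert out["gene_g4_content"]["non-cancer"]["median"] == 6
        assert out["gene_g4_content"]["cancer"]["median_per_kbp"] == pytest.approx(13.5)


class TestDbsnvNullStratification:
    def test_no_relation_column_is_flat_across_strata(self):
        """A planted no-relation SNV column shows stratum means that agree
        within sampling error, while the linear column separates sharply."""
        from g4snv.simulate import simulate_window_table

        tbl = simulate_window_table(seed=31)
        groups = [
            tbl.loc[tbl["g4_count"] == c, "dbsnv_count"] for c in range(16)
        ]
        means = np.array([g.mean() for g in groups])
        ses = np.array([g.std(ddof=1) / np.sqrt(len(g)) for g in groups])
        diff = np.abs(means[:, None] - means[None, :])
        se_pair = np.sqrt(ses[:, None] ** 2 + ses[None, :] ** 2)
        assert (diff <= 3 * se_pair + 1e-12).all()
        res = {r.group: r for r in stratify_enrichment(tbl, "cSNV")}
        assert res["10+"].mean > 3 * res["0"].mean
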