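"""Median-ratio copy-number estimation and genomic proportion."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tandemcn import copynumber, coverage, pipeline, simulate
from tandemcn.copynumber import (
    genomic_proportion,
    per_haploid_cn,
    single_copy_baseline,
)
from tandemcn.coverage import DepthTrack


def _track(feature, depths):
    return DepthTrack(feature, np.asarray(depths, dtype=int))


class TestBaseline:
    def test_balanced_two_exon_pool_gives_midpoint(self):
        tracks = [_track("a", [24] * 100), _track("b", [26] * 100)]
        assert single_copy_baseline(tracks) == 25.0

    def test_single_constant_exon(self):
        assert single_copy_baseline([_track("a", [30] * 10)]) == 30.0

    def test_pooled_median_is_length_weighted(self):
        # 100 bp at depth 10 vs 300 bp at depth 20: the longer exon dominates
        tracks = [_track("a", [10] * 100), _track("b", [20] * 300)]
        assert single_copy_baseline(tracks) == 20.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            single_copy_baseline([])


class TestPerHaploidCN:
    def test_ratio(self):
        assert per_haploid_cn(_track("g", [500] * 10), 25.0) == 20.0

    def test_identity_when_gene_matches_baseline(self):
        assert per_haploid_cn(_track("g", [25] * 10), 25.0) == 1.0

    def test_uncovered_gene_gives_zero(self):
        assert per_haploid_cn(_track("g", [0] * 10), 25.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            per_haploid_cn(_track("g", [5] * 10), 0.0)


class TestGenomicProportion:
    @pytest.mark.parametrize(
        "locus, genome, expected",
        [(50_000, 1_000_000, 5.0), (0, 1_000_000, 0.0), (21, 10_000, 0.21)],
    )
    def test_examples(self, locus, genome, expected):
        assert genomic_proportion(locus, genome) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            genomic_proportion(10, 0)
        with pytest.raises(ValueError):
            genomic_proportion(11, 10)


class TestBuildTable:
    def test_full_cohort_matrix_shape(self, default_products):
        table, proportions, _ = default_products
        assert table.values.shape == (26, 8)
        assert list(table.values.columns) == list(simulate.UNIT_GENES)
        assert len(proportions) == 26
        assert (table.baseline > 0).all()

    def test_missing_gene_is_nan_not_zero(self):
        tracks = {
            "L1": [_track("e1", [25] * 50), _track("18S", [500] * 50)],
        }
        table, _ = copynumber.build_table(tracks, ["e1"], ["18S", "28S"])
        assert table.values.loc["L1", "18S"] == 20.0
        assert np.isnan(table.values.loc["L1", "28S"])

    def test_lineage_without_exon_coverage_rejected(self):
        tracks = {"L1": [_track("18S", [500] * 50)]}
        with pytest.raises(ValueError, match="no retained-exon coverage"):
            copynumber.build_table(tracks, ["e1"], ["18S"])

    def test_ploidy_cancellation_doubling_all_depths(self):
        rng = np.random.default_rng(3)
        exon = rng.poisson(25, size=500)
        gene = rng.poisson(500, size=1000)
        tracks1 = {"L1": [DepthTrack("e1", exon), DepthTrack("18S", gene)]}
        tracks2 = {"L1": [DepthTrack("e1", exon * 2), DepthTrack("18S", gene * 2)]}
        t1, _ = copynumber.build_table(tracks1, ["e1"], ["18S"])
        t2, _ = copynumber.build_table(tracks2, ["e1"], ["18S"])
        assert t1.values.loc["L1", "18S"] == t2.values.loc["L1", "18S"]

    def test_roundtrip_through_tsv(self, default_products, tmp_path):
        table, _, _ = default_products
        path = tmp_path / "cn.tsv"
        copynumber.write_table(table, path)
        back = copynumber.read_table(path)
        pd.testing.assert_frame_equal(
            back.values.sort_index(),
            table.values.sort_index()[back.values.columns],
            check_exact=False,
            rtol=1e-4,
        )


class TestRecovery:
    def test_planted_copy_number_recovered_for_long_genes(self, long_gene_cohort,
                                                          long_gene_products):
        # >= 95% of lineage x gene cells within 10% of the planted value
        # (5S compared against its dropout-thinned expectation)
        table, _, _ = long_gene_products
        truth = long_gene_cohort.truth.set_index("lineage")
        cells = 0
        hits = 0
        for gene in simulate.UNIT_GENES:
            expected = truth["copy_number"].astype(float)
            if gene == "5S":
                expected = expected * (1 - truth["five_s_dropout"])
            rel = np.abs(table.values[gene] - expected) / expected
            cells += rel.notna().sum()
            hits += (rel < 0.10).sum()
        assert hits / cells >= 0.95

    def test_estimated_proportion_tracks_expected_proportion(
        self, long_gene_cohort, long_gene_products
    ):
        _, proportions, _ = long_gene_products
        truth = long_gene_cohort.truth.set_index("lineage")
        m = proportions.set_index("lineage")
        rel = np.abs(m["proportion"] - truth["expected_proportion"]) / truth[
            "expected_proportion"
        ]
        assert (rel < 0.10).all()

    def test_5s_estimate_reflects_planted_dropout(self):
        cfg = simulate.SimulationConfig(seed=31, five_s_dropout_range=(0.1, 0.1))
        sim = simulate.simulate_all(cfg, template=simulate.long_gene_template())
        table, _, _ = pipeline.quantify(sim)
        ratio = table.values["5S"] / table.values["18S"]
        assert np.allclose(ratio, 0.9, rtol=0.10)

    def test_within_clone_replicates_are_tightly_reproducible(self):
        # three sequencing replicates of the same lineage (fresh noise, same
        # planted copy number) should agree to a CV below 5%
        base = simulate.SimulationConfig(seed=41)
        template = simulate.long_gene_template()
        reference = simulate.build_reference(
            template, base, np.random.default_rng(41)
        )
        lineage = simulate.LineageSpec(
            lineage_id="CLONE",
            mode="asexual",
            ploidy=3,
            population="Grasmere",
            copy_number=150,
            five_s_dropout=0.05,
        )
        estimates = []
        for rep_seed in (1, 2, 3):
            depth, _ = simulate.simulate_depths(
                reference, lineage, base, np.random.default_rng(rep_seed)
            )
            tracks = {"CLONE": coverage.tracks_from_frame(depth, "CLONE")}
            exons = reference.candidate_exons
            retained = exons.loc[exons["copy_factor"] == 1.0, "exon_id"].tolist()
            table, _ = copynumber.build_table(
                tracks, retained, simulate.UNIT_GENES
            )
            estimates.append(table.values.loc["CLONE"])
        est = pd.DataFrame(estimates)
        cv = est.std(ddof=1) / est.mean()
        assert (cv < 0.05).all()
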