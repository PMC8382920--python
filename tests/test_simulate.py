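"""The synthetic-data generator: structure, noise model, determinism."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from tandemcn import simulate
from tandemcn.simulate import (
    GeneSpan,
    LineageSpec,
    SimulationConfig,
    UnitTemplate,
    default_template,
    long_gene_template,
)


class TestUnitTemplate:
    def test_default_unit_is_13kb_with_each_gene_once(self):
        tpl = default_template()
        assert tpl.unit_length == 13_000
        layout = tpl.layout()
        assert sorted(layout["gene"]) == sorted(simulate.UNIT_GENES)
        # layout is non-overlapping and ordered
        assert (layout["end"] >= layout["start"]).all()
        assert (layout["start"].to_numpy()[1:] > layout["end"].to_numpy()[:-1]).all()

    def test_long_gene_template_keeps_period_and_floors_lengths(self):
        tpl = long_gene_template(1000)
        assert tpl.unit_length == 13_000
        assert all(g.length >= 1000 for g in tpl.genes)

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            UnitTemplate(genes=(), spacers=())

    def test_duplicate_gene_rejected(self):
        g = GeneSpan("18S", 100, "+")
        with pytest.raises(ValueError, match="once"):
            UnitTemplate(genes=(g, g), spacers=(10, 10))


class TestBuildReference:
    def test_masked_locus_spans_exactly_one_unit(self):
        cfg = SimulationConfig(seed=1)
        ref = simulate.build_reference(default_template(), cfg)
        scaffold, start, end = ref.masked_locus
        assert end - start + 1 == 13_000

    def test_requested_exon_count_and_min_length(self):
        cfg = SimulationConfig(seed=1, n_exons=10)
        ref = simulate.build_reference(default_template(), cfg)
        assert len(ref.candidate_exons) == 10
        assert (ref.candidate_exons["length"] >= cfg.min_exon_length).all()

    def test_zero_exons_is_a_configuration_error(self):
        cfg = SimulationConfig(seed=1, n_exons=0)
        with pytest.raises(ValueError, match="zero"):
            simulate.build_reference(default_template(), cfg)

    def test_tandem_units_are_exact_translations(self):
        cfg = SimulationConfig(seed=1, n_units=3)
        ref = simulate.build_reference(default_template(), cfg)
        ug = ref.unit_genes
        for u in (1, 2):
            shifted = ug[ug["unit_index"] == u].reset_index(drop=True)
            base = ug[ug["unit_index"] == 0].reset_index(drop=True)
            assert (shifted["start"] - base["start"] == u * 13_000).all()


class TestCohort:
    def test_default_cohort_has_26_lineages(self):
        specs, tree, truth = simulate.simulate_cohort(SimulationConfig(seed=2))
        assert len(specs) == 26
        assert sum(s.mode == "sexual" for s in specs) == 10
        assert sum(s.mode == "asexual" for s in specs) == 16
        assert len(truth) == 26

    def test_same_seed_gives_identical_cohorts(self):
        a = simulate.simulate_cohort(SimulationConfig(seed=3))
        b = simulate.simulate_cohort(SimulationConfig(seed=3))
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[2], b[2])
        assert a[1].as_string(schema="newick") == b[1].as_string(schema="newick")

    def test_disjoint_ranges_separate_modes_completely(self):
        cfg = SimulationConfig(
            seed=4, cn_range_sexual=(10, 30), cn_range_asexual=(100, 300)
        )
        specs, _, _ = simulate.simulate_cohort(cfg)
        sexual = [s.copy_number for s in specs if s.mode == "sexual"]
        asexual = [s.copy_number for s in specs if s.mode == "asexual"]
        assert max(sexual) < min(asexual)

    def test_truth_proportion_matches_closed_form(self):
        cfg = SimulationConfig(seed=5)
        _, _, truth = simulate.simulate_cohort(cfg)
        L = default_template().unit_length
        expected = 100.0 * truth["copy_number"] * L / (
            cfg.background_length + truth["copy_number"] * L
        )
        np.testing.assert_allclose(truth["expected_proportion"], expected)

    def test_tree_tips_match_lineages_with_positive_depths(self):
        specs, tree, _ = simulate.simulate_cohort(SimulationConfig(seed=6))
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert tips == {s.lineage_id for s in specs}
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() > 0

    def test_asexual_lineages_span_multiple_clades(self):
        # asexuality must not be monophyletic: the GEE correction is only
        # exercised when modes are clustered but repeatedly derived
        specs, tree, _ = simulate.simulate_cohort(SimulationConfig(seed=7))
        asexual = {s.lineage_id for s in specs if s.mode == "asexual"}
        maximal = 0
        for node in tree.preorder_node_iter():
            tips = {l.taxon.label for l in node.leaf_iter()}
            if tips <= asexual:
                parent = node.parent_node
                ptips = {l.taxon.label for l in parent.leaf_iter()} if parent else set()
                if not ptips <= asexual:
                    maximal += 1
        assert maximal >= 3


class TestDepthModel:
    def _lineage(self, cn, drop=0.0):
        return LineageSpec(
            lineage_id="L1",
            mode="sexual",
            ploidy=2,
            population="P",
            copy_number=cn,
            five_s_dropout=drop,
        )

    def test_poisson_limit_recovers_base_depth(self):
        # dispersion -> inf collapses to Poisson; LLN at n = 10,000 bases
        cfg = SimulationConfig(
            seed=8,
            dispersion=math.inf,
            exon_dispersion_range=(math.inf, math.inf),
            n_exons=5,
            min_exon_length=2000,
            max_exon_length=2000,
            outlier_factors=(),
        )
        ref = simulate.build_reference(default_template(), cfg)
        table, _ = simulate.simulate_depths(
            ref, self._lineage(1), cfg, np.random.default_rng(8)
        )
        exon_ids = set(ref.candidate_exons["exon_id"])
        depths = table[table["feature"].isin(exon_ids)]["depth"].to_numpy()
        assert depths.size == 10_000
        se = depths.std(ddof=1) / np.sqrt(depths.size)
        assert abs(depths.mean() - cfg.base_depth) < 3 * se

    def test_unit_gene_median_tracks_planted_copy_number(self):
        cfg = SimulationConfig(seed=9)
        ref = simulate.build_reference(default_template(), cfg)
        table, _ = simulate.simulate_depths(
            ref, self._lineage(20), cfg, np.random.default_rng(9)
        )
        med = table[table["feature"] == "28S"]["depth"].median()
        assert med == pytest.approx(500, rel=0.05)

    def test_zero_dropout_gives_5s_the_shared_unit_mean(self):
        cfg = SimulationConfig(seed=10)
        ref = simulate.build_reference(default_template(), cfg)
        table, _ = simulate.simulate_depths(
            ref, self._lineage(50, drop=0.0), cfg, np.random.default_rng(10)
        )
        m5s = table[table["feature"] == "5S"]["depth"].mean()
        m28 = table[table["feature"] == "28S"]["depth"].mean()
        assert m5s == pytest.approx(m28, rel=0.15)

    def test_read_counts_consistent_with_expected_proportion(self):
        cfg = SimulationConfig(seed=12)
        ref = simulate.build_reference(default_template(), cfg)
        lineage = self._lineage(100)
        _, counts = simulate.simulate_depths(
            ref, lineage, cfg, np.random.default_rng(12)
        )
        got = 100.0 * counts["reads_locus"] / counts["reads_genome"]
        expected = simulate.expected_proportion(100, 13_000, cfg.background_length)
        assert got == pytest.approx(expected, rel=0.05)


def test_written_cohort_is_byte_identical_across_runs(tmp_path):
    cfg = SimulationConfig(seed=21, n_exons=6)
    for d in ("a", "b"):
        simulate.write_cohort(simulate.simulate_all(cfg), tmp_path / d)
    files_a = sorted((tmp_path / "a").rglob("*"))
    files_b = sorted((tmp_path / "b").rglob("*"))
    assert [f.name for f in files_a] == [f.name for f in files_b]
    for fa, fb in zip(files_a, files_b):
        if fa.is_file():
            assert fa.read_bytes() == fb.read_bytes(), fa.name
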