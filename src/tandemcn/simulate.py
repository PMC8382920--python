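"""Synthetic cohorts for the tandem rDNA-histone copy-number pipeline.

Real inputs to the pipeline are per-base depth tables from whole-genome
short-read libraries of snail lineages, a gene-model table of candidate
single-copy exons, homology hits of the eight repeat-unit genes against an
assembly, mapped-read totals, and a lineage phylogeny.  This module generates
all of those de novo, with the statistical structure the downstream estimators
assume, so the whole pipeline is testable at desk scale:

* a tandem repeat unit (~13 kb) carrying 18S-5.8S-28S, 5S and the four core
  histones, replicated ``n_units`` times on one scaffold;
* background "genes" whose longest exons serve as single-copy normalisers,
  including planted high-copy decoys that the selection stage must reject;
* per-base depth drawn negative-binomially around ``base_depth`` for
  single-copy sequence and ``base_depth * copy_number`` for unit genes
  (5S thinned by a per-lineage dropout fraction, mimicking units that lack 5S);
* a random bifurcating tree in which asexual lineages occupy several separate
  clades, reproducing the multiple-origins confound the phylogenetic GEE is
  meant to absorb;
* a truth table (planted copy numbers and expected genomic proportions) that
  downstream tests use as the oracle.

Everything is driven by a single integer seed; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

UNIT_GENES = ("18S", "5.8S", "28S", "5S", "H2A", "H2B", "H3", "H4")

#: genes transcribed as the 45S precursor plus the core histones; these share
#: the unit copy number exactly (5S is the one gene subject to dropout)
SHARED_UNIT_GENES = ("18S", "5.8S", "28S", "H2A", "H2B", "H3", "H4")

REPEAT_SCAFFOLD = "repeat_scaffold"


@dataclass(frozen=True)
class GeneSpan:
    name: str
    length: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class UnitTemplate:
    """Gene order, lengths, orientations and spacers of one tandem unit.

    ``spacers[i]`` is the intergenic gap following ``genes[i]`` (the last
    spacer pads the unit out to its full period).
    """

    genes: tuple[GeneSpan, ...]
    spacers: tuple[int, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) == 0:
            raise ValueError("unit template must contain at least one gene")
        if len(set(names)) != len(names):
            raise ValueError("each gene may appear only once per unit")
        unknown = set(names) - set(UNIT_GENES)
        if unknown:
            raise ValueError(f"unknown unit genes: {sorted(unknown)}")
        if len(self.spacers) != len(self.genes):
            raise ValueError("need one spacer per gene (after each gene)")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacer lengths must be non-negative")
        if any(g.length < 1 for g in self.genes):
            raise ValueError("gene lengths must be positive")
        if any(g.strand not in "+-" for g in self.genes):
            raise ValueError("gene strand must be '+' or '-'")

    @property
    def unit_length(self) -> int:
        return sum(g.length for g in self.genes) + sum(self.spacers)

    def layout(self) -> pd.DataFrame:
        """1-based inclusive gene coordinates within one unit."""
        rows = []
        pos = 1
        for gene, spacer in zip(self.genes, self.spacers):
            rows.append(
                {
                    "gene": gene.name,
                    "start": pos,
                    "end": pos + gene.length - 1,
                    "strand": gene.strand,
                    "length": gene.length,
                }
            )
            pos += gene.length + spacer
        return pd.DataFrame(rows)


def default_template() -> UnitTemplate:
    """The default ~13 kb unit: 45S cluster, then 5S and the histone quartet.

    Gene lengths are typical for animal rRNA/core-histone genes; spacers pad
    the unit to a 13,000 bp period.  Orientations are free parameters of the
    simulation (the architecture module infers them, whatever they are).
    """
    genes = (
        GeneSpan("18S", 1800, "+"),
        GeneSpan("5.8S", 160, "+"),
        GeneSpan("28S", 3500, "+"),
        GeneSpan("5S", 120, "+"),
        GeneSpan("H2A", 400, "-"),
        GeneSpan("H2B", 400, "+"),
        GeneSpan("H3", 400, "-"),
        GeneSpan("H4", 300, "+"),
    )
    spacers = (300, 400, 1500, 900, 700, 700, 700, 720)
    return UnitTemplate(genes=genes, spacers=spacers)


def long_gene_template(min_gene_length: int = 1000) -> UnitTemplate:
    """A 13 kb unit variant in which every gene is at least ``min_gene_length``.

    Median-ratio estimates over very short genes (the 160 bp 5.8S, 120 bp 5S)
    carry more sampling noise than long ones; benchmarks of estimator accuracy
    use this variant so that feature length is not the limiting factor.
    """
    base = default_template()
    genes = tuple(
        GeneSpan(g.name, max(g.length, min_gene_length), g.strand) for g in base.genes
    )
    gene_total = sum(g.length for g in genes)
    if gene_total > 13000:
        raise ValueError("gene lengths exceed the 13 kb unit")
    pad = 13000 - gene_total
    n = len(genes)
    spacers = tuple(pad // n + (1 if i < pad % n else 0) for i in range(n))
    return UnitTemplate(genes=genes, spacers=spacers)


@dataclass(frozen=True)
class LineageSpec:
    """One simulated lineage with its planted (true) repeat copy number."""

    lineage_id: str
    mode: str  # 'sexual' | 'asexual'
    ploidy: int
    population: str
    copy_number: int  # per-haploid tandem unit copies
    five_s_dropout: float  # fraction of units lacking 5S

    def __post_init__(self) -> None:
        if self.mode not in ("sexual", "asexual"):
            raise ValueError("mode must be 'sexual' or 'asexual'")
        if self.ploidy not in (2, 3, 4):
            raise ValueError("ploidy must be 2, 3 or 4")
        if self.copy_number < 1:
            raise ValueError("copy number must be >= 1")
        if not 0.0 <= self.five_s_dropout <= 1.0:
            raise ValueError("5S dropout fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-shaped defaults.

    The default cohort mirrors the study design this pipeline targets:
    10 sexual diploid lineages versus 16 asexual lineages (11 triploid,
    5 tetraploid), repeat copy numbers drawn from well separated ranges, a
    60 Mb single-copy background chosen so that expected genomic proportions
    of the repeat fall in the fraction-of-a-percent (sexual) to several
    percent (asexual) regime, and two planted high-copy decoy exons at 11x
    and 15x single-copy depth for the outlier filter to catch.
    """

    n_sexual: int = 10
    n_asexual_triploid: int = 11
    n_asexual_tetraploid: int = 5
    background_length: int = 60_000_000
    n_exons: int = 40
    min_exon_length: int = 300
    max_exon_length: int = 2000
    base_depth: float = 25.0
    dispersion: float = 10.0
    exon_dispersion_range: tuple[float, float] = (5.0, 500.0)
    cn_range_sexual: tuple[int, int] = (10, 30)
    cn_range_asexual: tuple[int, int] = (100, 300)
    five_s_dropout_range: tuple[float, float] = (0.0, 0.15)
    outlier_factors: tuple[float, ...] = (11.0, 15.0)
    n_units: int = 3
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_sexual, self.n_asexual_triploid, self.n_asexual_tetraploid)
        if any(c < 0 for c in counts):
            raise ValueError("lineage counts must be >= 0")
        if self.base_depth <= 0:
            raise ValueError("base depth must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive (math.inf for Poisson)")
        lo, hi = self.exon_dispersion_range
        if not (0 < lo <= hi):
            raise ValueError("exon dispersion range must be positive and ordered")
        for lo, hi in (self.cn_range_sexual, self.cn_range_asexual):
            if not (1 <= lo <= hi):
                raise ValueError("copy-number ranges must be non-empty with lo >= 1")
        lo, hi = self.five_s_dropout_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("5S dropout range must lie within [0, 1]")
        if self.n_exons < 0:
            raise ValueError("number of exons must be >= 0")
        if self.min_exon_length < 1 or self.max_exon_length < self.min_exon_length:
            raise ValueError("invalid exon length range")
        if self.n_units < 1:
            raise ValueError("need at least one tandem unit")
        if self.background_length <= 0 or self.read_length <= 0:
            raise ValueError("background length and read length must be positive")

    @property
    def n_lineages(self) -> int:
        return self.n_sexual + self.n_asexual_triploid + self.n_asexual_tetraploid


@dataclass
class Reference:
    """Simulated reference bundle: scaffolds, annotations, masked locus."""

    template: UnitTemplate
    n_units: int
    sequences: dict[str, str]
    unit_genes: pd.DataFrame  # scaffold, gene, unit_index, start, end, strand
    gene_models: pd.DataFrame  # gene_id, exon_id, scaffold, start, end, length
    candidate_exons: pd.DataFrame  # exon_id, length, copy_factor
    masked_locus: tuple[str, int, int]  # scaffold, start, end (1-based inclusive)

    @property
    def unit_length(self) -> int:
        return self.template.unit_length


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_reference(
    template: UnitTemplate, config: SimulationConfig, rng: np.random.Generator | None = None
) -> Reference:
    """Build the synthetic reference: repeat scaffold plus exon scaffolds.

    The repeat scaffold carries ``config.n_units`` exact tandem copies of the
    unit; the masked-locus span is the first full unit.  Each background gene
    gets its own scaffold holding an intended candidate exon (length drawn
    from the configured range) plus one or two shorter decoy exons, so the
    longest-exon selection rule has something to do.  The first
    ``len(config.outlier_factors)`` genes carry planted high-copy exons.
    """
    if config.n_exons == 0:
        raise ValueError("configuration requests zero candidate exons")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    layout = template.layout()
    unit_len = template.unit_length
    unit_rows = []
    for u in range(config.n_units):
        offset = u * unit_len
        for row in layout.itertuples():
            unit_rows.append(
                {
                    "scaffold": REPEAT_SCAFFOLD,
                    "gene": row.gene,
                    "unit_index": u,
                    "start": row.start + offset,
                    "end": row.end + offset,
                    "strand": row.strand,
                }
            )
    unit_genes = pd.DataFrame(unit_rows)

    sequences = {REPEAT_SCAFFOLD: _random_sequence(rng, config.n_units * unit_len)}

    model_rows = []
    exon_rows = []
    factors = list(config.outlier_factors)
    k_lo, k_hi = config.exon_dispersion_range
    for i in range(config.n_exons):
        gene_id = f"g{i:03d}"
        scaffold = f"bg_{gene_id}"
        if i < len(factors):
            # planted high-copy decoys: evenly covered (clean mapping) but
            # duplicated, so they survive concordance and must be caught by
            # the outlier rule instead
            target_len = config.max_exon_length
            copy_factor = float(factors[i])
            exon_k = k_hi
        else:
            target_len = int(
                rng.integers(config.min_exon_length, config.max_exon_length + 1)
            )
            copy_factor = 1.0
            # per-exon coverage evenness (mappability/GC): log-uniform
            # dispersion; only the high-dispersion tail is "evenly covered"
            # enough to survive the mean/median/mode filter
            if math.isfinite(k_lo) and k_lo < k_hi:
                exon_k = float(np.exp(rng.uniform(np.log(k_lo), np.log(k_hi))))
            else:
                exon_k = float(k_lo)
        n_decoys = int(rng.integers(1, 3))
        decoy_lens = [
            int(rng.integers(50, max(51, target_len))) for _ in range(n_decoys)
        ]
        pos = 1
        exon_id = ""
        pieces = decoy_lens[: n_decoys // 2] + [target_len] + decoy_lens[n_decoys // 2 :]
        j = 0
        for piece in pieces:
            j += 1
            eid = f"{gene_id}.e{j}"
            model_rows.append(
                {
                    "gene_id": gene_id,
                    "exon_id": eid,
                    "scaffold": scaffold,
                    "start": pos,
                    "end": pos + piece - 1,
                    "length": piece,
                }
            )
            if piece == target_len and not exon_id:
                exon_id = eid
            pos += piece + int(rng.integers(80, 400))
        exon_rows.append(
            {
                "exon_id": exon_id,
                "length": target_len,
                "copy_factor": copy_factor,
                "dispersion": exon_k,
            }
        )
        sequences[scaffold] = _random_sequence(rng, pos - 1)

    gene_models = pd.DataFrame(model_rows)
    candidate_exons = pd.DataFrame(exon_rows)
    masked_locus = (REPEAT_SCAFFOLD, 1, unit_len)
    return Reference(
        template=template,
        n_units=config.n_units,
        sequences=sequences,
        unit_genes=unit_genes,
        gene_models=gene_models,
        candidate_exons=candidate_exons,
        masked_locus=masked_locus,
    )


def expected_proportion(copy_number: float, unit_length: int, background_length: int) -> float:
    """Expected percent of mapped reads attributable to the repeat locus."""
    repeat = copy_number * unit_length
    return 100.0 * repeat / (background_length + repeat)


def _join_random(
    nodes: list[dendropy.Node], rng: np.random.Generator, scale: float
) -> dendropy.Node:
    """Coalescent-style random sequential pairing with exponential branches."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = (child.edge.length or 0.0) + float(
                rng.exponential(scale)
            ) + 1e-3
        nodes.append(parent)
    return nodes[0]


def simulate_tree(
    lineages: Sequence[LineageSpec], rng: np.random.Generator, n_asexual_clades: int = 3
) -> dendropy.Tree:
    """Random bifurcating tree with asexual lineages clustered in >= 3 clades.

    Obligate asexuality in the target system arose repeatedly, so asexual tips
    must not form one clade: they are split into ``n_asexual_clades`` groups,
    each grown as its own random subtree, and the clades (plus sexual clades)
    are then joined by a random backbone.  Branch lengths are exponential,
    shorter within clades than between them.
    """
    sexual = [l.lineage_id for l in lineages if l.mode == "sexual"]
    asexual = [l.lineage_id for l in lineages if l.mode == "asexual"]
    taxa = dendropy.TaxonNamespace([l.lineage_id for l in lineages])
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.edge.length = 0.0
        return node

    def split(labels: list[str], k: int) -> list[list[str]]:
        labels = list(labels)
        rng.shuffle(labels)
        k = min(k, len(labels)) or 1
        bounds = np.linspace(0, len(labels), k + 1).astype(int)
        return [labels[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    asex_roots = [
        _join_random([leaf(x) for x in group], rng, scale=0.08)
        for group in split(asexual, n_asexual_clades)
    ]
    sex_roots = [
        _join_random([leaf(x) for x in group], rng, scale=0.08)
        for group in split(sexual, 2)
    ]
    # interleave clades on a backbone so no two asexual clades are sisters:
    # each asexual clade then reads as a separate origin of asexuality
    ordered: list[dendropy.Node] = []
    while asex_roots or sex_roots:
        if asex_roots:
            ordered.append(asex_roots.pop())
        if sex_roots:
            ordered.append(sex_roots.pop())
    root = ordered[0]
    for clade in ordered[1:]:
        parent = dendropy.Node()
        for child in (root, clade):
            parent.add_child(child)
            child.edge.length = (child.edge.length or 0.0) + float(
                rng.exponential(0.4)
            ) + 1e-3
        root = parent
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def simulate_cohort(
    config: SimulationConfig,
    template: UnitTemplate | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LineageSpec], dendropy.Tree, pd.DataFrame]:
    """Draw a cohort of lineage specs, a phylogeny, and the truth table.

    Copy numbers are uniform integers from the mode-specific ranges; the 5S
    dropout fraction is uniform in its configured range.  The truth table
    records the planted values plus each lineage's expected genomic
    proportion of repeat sequence.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    template = default_template() if template is None else template
    populations = [
        "Alexandrina", "Brunner", "Grasmere", "Haupiri", "Heron", "Ianthe",
        "Kaniere", "Mapourika", "Mavora", "Poerua", "Rotoiti", "Selfe",
    ]

    specs: list[LineageSpec] = []

    def draw(mode: str, ploidy: int, prefix: str, count: int) -> None:
        lo, hi = (
            config.cn_range_sexual if mode == "sexual" else config.cn_range_asexual
        )
        for i in range(count):
            cn = int(rng.integers(lo, hi + 1))
            f_lo, f_hi = config.five_s_dropout_range
            drop = float(rng.uniform(f_lo, f_hi))
            pop = populations[int(rng.integers(len(populations)))]
            specs.append(
                LineageSpec(
                    lineage_id=f"{prefix}{i + 1:02d}",
                    mode=mode,
                    ploidy=ploidy,
                    population=pop,
                    copy_number=cn,
                    five_s_dropout=drop,
                )
            )

    draw("sexual", 2, "SEX", config.n_sexual)
    draw("asexual", 3, "TRI", config.n_asexual_triploid)
    draw("asexual", 4, "TET", config.n_asexual_tetraploid)

    tree = simulate_tree(specs, rng)
    truth = pd.DataFrame(
        {
            "lineage": [s.lineage_id for s in specs],
            "mode": [s.mode for s in specs],
            "ploidy": [s.ploidy for s in specs],
            "copy_number": [s.copy_number for s in specs],
            "five_s_dropout": [s.five_s_dropout for s in specs],
            "expected_proportion": [
                expected_proportion(
                    s.copy_number, template.unit_length, config.background_length
                )
                for s in specs
            ],
        }
    )
    return specs, tree, truth


def _draw_depths(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Per-base depth: NB(mean, k) with variance mean + mean^2/k; Poisson at k=inf."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if math.isinf(dispersion):
        return rng.poisson(mean, size=size)
    k = dispersion
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def simulate_depths(
    reference: Reference,
    lineage: LineageSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Per-base depth for unit genes and candidate exons, plus read totals.

    Depth at a single-copy exon base is NB(base_depth * copy_factor, k); at a
    unit-gene base NB(base_depth * copy_number, k), with the 5S mean thinned by
    the lineage's dropout fraction.  Mapped-read totals are Poisson draws whose
    expected ratio equals the truth-table genomic proportion (read totals scale
    with ploidy, but the locus/genome ratio does not).
    """
    frames = []
    layout = reference.template.layout()
    for row in layout.itertuples():
        cn = float(lineage.copy_number)
        if row.gene == "5S":
            cn *= 1.0 - lineage.five_s_dropout
        depths = _draw_depths(rng, config.base_depth * cn, config.dispersion, row.length)
        frames.append(
            pd.DataFrame(
                {
                    "feature": row.gene,
                    "position": np.arange(1, row.length + 1),
                    "depth": depths,
                }
            )
        )
    for exon in reference.candidate_exons.itertuples():
        depths = _draw_depths(
            rng,
            config.base_depth * exon.copy_factor,
            float(exon.dispersion),
            int(exon.length),
        )
        frames.append(
            pd.DataFrame(
                {
                    "feature": exon.exon_id,
                    "position": np.arange(1, int(exon.length) + 1),
                    "depth": depths,
                }
            )
        )
    depth_table = pd.concat(frames, ignore_index=True)

    unit_len = reference.unit_length
    prop = expected_proportion(
        lineage.copy_number, unit_len, config.background_length
    )
    total_bp = lineage.ploidy * (
        config.background_length + lineage.copy_number * unit_len
    )
    exp_genome = config.base_depth * total_bp / config.read_length
    exp_locus = exp_genome * prop / 100.0
    reads_genome = int(rng.poisson(exp_genome))
    reads_locus = int(min(rng.poisson(exp_locus), reads_genome))
    counts = {
        "lineage": lineage.lineage_id,
        "reads_locus": reads_locus,
        "reads_genome": reads_genome,
    }
    return depth_table, counts


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    reference: Reference
    lineages: list[LineageSpec]
    tree: dendropy.Tree
    truth: pd.DataFrame
    depth_tables: dict[str, pd.DataFrame]
    read_counts: pd.DataFrame

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage": [l.lineage_id for l in self.lineages],
                "mode": [l.mode for l in self.lineages],
                "ploidy": [l.ploidy for l in self.lineages],
                "population": [l.population for l in self.lineages],
            }
        )


def simulate_all(
    config: SimulationConfig, template: UnitTemplate | None = None
) -> SimulatedCohort:
    """Run the full simulation: reference, cohort, per-lineage depth tables.

    Per-lineage RNG streams are spawned from the config seed, so adding or
    reordering downstream consumers cannot perturb the draws.
    """
    template = default_template() if template is None else template
    ss = np.random.SeedSequence(config.seed)
    ref_seq, cohort_seq, depth_seq = ss.spawn(3)
    reference = build_reference(template, config, np.random.default_rng(ref_seq))
    lineages, tree, truth = simulate_cohort(
        config, template, np.random.default_rng(cohort_seq)
    )
    depth_tables = {}
    counts = []
    for lineage, child in zip(lineages, depth_seq.spawn(len(lineages))):
        table, cnt = simulate_depths(
            reference, lineage, config, np.random.default_rng(child)
        )
        depth_tables[lineage.lineage_id] = table
        counts.append(cnt)
    read_counts = pd.DataFrame(counts)
    return SimulatedCohort(
        config=config,
        reference=reference,
        lineages=lineages,
        tree=tree,
        truth=truth,
        depth_tables=depth_tables,
        read_counts=read_counts,
    )


def brownian_copy_numbers(
    tree: dendropy.Tree,
    rng: np.random.Generator,
    sigma2: float = 0.1,
    root_copy_number: float = 50.0,
    mode_by_lineage: Mapping[str, str] | None = None,
    asexual_log_effect: float = 0.0,
) -> pd.Series:
    """Copy numbers evolving by Brownian motion on the log scale along a tree.

    Each edge contributes an independent Normal(0, sigma2 * length) increment
    to log copy number, so tip covariances equal sigma2 times shared branch
    length -- the correlation structure the phylogenetic GEE assumes.  An
    optional multiplicative mode effect (``exp(asexual_log_effect)``) is
    applied to asexual tips; with the default 0 the trait is mode-free, which
    is the null used to calibrate the GEE's type-I error.  The default BM
    rate is chosen so that the marginal within-mode spread of copy number
    (log-sd ~0.3-0.45 at the cohort trees' typical root-to-tip depths)
    matches the roughly threefold within-mode range the estimator sees in
    real cohorts.
    """
    if sigma2 < 0:
        raise ValueError("BM rate must be non-negative")
    values: dict[str, float] = {}
    stack = [(tree.seed_node, math.log(root_copy_number))]
    while stack:
        node, value = stack.pop()
        for child in node.child_nodes():
            edge = child.edge.length or 0.0
            child_value = value + math.sqrt(sigma2 * edge) * rng.standard_normal()
            if child.is_leaf():
                values[child.taxon.label] = child_value
            else:
                stack.append((child, child_value))
    if tree.seed_node.is_leaf():
        values[tree.seed_node.taxon.label] = math.log(root_copy_number)
    out = pd.Series(values)
    if mode_by_lineage is not None and asexual_log_effect:
        asex = out.index.map(lambda l: mode_by_lineage[l] == "asexual")
        out[np.asarray(asex)] += asexual_log_effect
    return np.exp(out)


def blast_hits_from_reference(
    reference: Reference, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Exact homology hits of each unit gene against the repeat scaffold.

    Emits a BLAST tabular (outfmt-6 style) frame with one perfect hit per gene
    copy; minus-strand hits are encoded, as BLAST does, by subject start >
    subject end.  Used to exercise the architecture module against a reference
    whose true unit period is known.
    """
    rows = []
    for row in reference.unit_genes.itertuples():
        sstart, send = (
            (row.start, row.end) if row.strand == "+" else (row.end, row.start)
        )
        length = row.end - row.start + 1
        rows.append(
            {
                "qseqid": row.gene,
                "sseqid": row.scaffold,
                "pident": 100.0,
                "length": length,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": 1,
                "qend": length,
                "sstart": sstart,
                "send": send,
                "evalue": 0.0,
                "bitscore": 2.0 * length,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers -- all plain text, deterministic, 1-based inclusive coordinates


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cohort(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the whole simulation to disk in the pipeline's input dialects."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    depth_dir = outdir / "depth"
    depth_dir.mkdir(exist_ok=True)

    paths: dict[str, Path] = {}

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sim.reference.sequences.items())
    ]
    paths["reference_fasta"] = outdir / "reference.fasta"
    SeqIO.write(records, paths["reference_fasta"], "fasta")

    paths["gene_models"] = outdir / "gene_models.tsv"
    _write_tsv(sim.reference.gene_models, paths["gene_models"])
    paths["unit_genes"] = outdir / "unit_genes.tsv"
    _write_tsv(sim.reference.unit_genes, paths["unit_genes"])
    paths["blast_hits"] = outdir / "blast_hits.tsv"
    hits = blast_hits_from_reference(sim.reference)
    hits.to_csv(paths["blast_hits"], sep="\t", index=False, header=False)

    scaffold, start, end = sim.reference.masked_locus
    paths["masked_locus"] = outdir / "masked_locus.tsv"
    _write_tsv(
        pd.DataFrame([{"scaffold": scaffold, "start": start, "end": end}]),
        paths["masked_locus"],
    )

    for lineage_id, table in sim.depth_tables.items():
        _write_tsv(table, depth_dir / f"{lineage_id}.depth.tsv")
    paths["depth_dir"] = depth_dir

    paths["read_counts"] = outdir / "read_counts.tsv"
    _write_tsv(sim.read_counts, paths["read_counts"])
    paths["metadata"] = outdir / "lineages.tsv"
    _write_tsv(sim.metadata, paths["metadata"])
    paths["truth"] = outdir / "truth.tsv"
    _write_tsv(sim.truth, paths["truth"])
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(
        sim.tree.as_string(schema="newick", suppress_rooting=True)
    )
    return paths
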