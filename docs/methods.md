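# Methods

This note records the models behind `tandemcn`, the parameters that matter,
what the synthetic cohorts do and do not emulate, and the numerical and
design choices made where the problem left them open.

## The estimator

Per-haploid copy number of a repeat gene is the ratio of two median depths:

```
CN(l, g) = median_b depth_l(g, b)  /  median_b depth_l(pooled retained exons, b)
```

The denominator pools the per-base depths of all retained single-copy exons
into one multiset before taking the median (not a mean of per-exon medians),
so longer exons carry proportionally more weight and the baseline is the
median depth of the combined single-copy reference. Medians rather than
means make both terms robust to coverage spikes. Sequencing effort and
ploidy multiply numerator and denominator alike, so the ratio is per haploid
genome; the test suite checks this cancellation exactly (doubling every
depth leaves estimates unchanged).

Genomic proportion is `100 × reads_locus / reads_genome` for reads mapped to
one masked copy of the unit versus the whole assembly, reported as percent.
Missing genes are explicit missing values, never zero: zero is a meaningful
copy-number estimate.

## The single-copy filter chain

1. *Candidates*: the longest exon of each candidate gene, at least 300 bp
   (length ties resolve to the first exon in coordinate order).
2. *Concordance*: within a lineage, an exon passes when
   `max(mean, median, mode) ≤ 1.10 × min(mean, median, mode)`. "Within 10%
   of each other" is interpreted as this range criterion, which dominates
   every pairwise comparison. When the smallest statistic is 0, the exon
   passes only if all three are 0. The depth mode is the most frequent
   integer depth, ties broken to the smallest value (deterministic and
   test-stable; multi-modal depth distributions have no canonical mode).
   Medians of even-length tracks use the midpoint convention.
3. *Retention*: pass in at least `ceil(20/27 × n)` of the `n` lineages —
   the 20-of-27 stringency rescaled to other cohort sizes.
4. *Outlier screen*: compute each retained exon's cross-lineage median
   depth; exons above `factor` (default 2.0) times the median of those
   medians are evenly covered but multi-copy and are excluded, with the fold
   factor reported. The factor threshold formalises an originally ad hoc
   exclusion of ~11× and ~15× exons and recovers such cases by a wide
   margin; with fewer than three exons no screen is attempted (warning).
   The screen is a fixed point on realistic inputs (single-copy medians
   cluster tightly around the lineage depth), which the tests verify.

## The synthetic cohort

The generator exists so that every downstream stage can be tested against a
planted truth at desk scale. Defaults are study-shaped and fixed once:

- **Cohort**: 10 sexual diploid, 11 asexual triploid, 5 asexual tetraploid
  lineages. Planted per-haploid unit copy numbers are uniform integers,
  sexual 10–30 and asexual 100–300; with a 60 Mb single-copy background and
  a 13 kb unit these give expected genomic proportions of ~0.2–0.65%
  (sexual) and ~2–6% (asexual), the fraction-of-a-percent versus
  several-percent regime the estimator must resolve.
- **Unit**: 13,000 bp carrying 18S (1800), 5.8S (160), 28S (3500), 5S
  (120), H2A/H2B/H3 (400 each), H4 (300) plus spacers; gene lengths are
  typical, not measured, values. A `long_gene_template()` variant pads every
  gene to ≥ 1 kb (same 13 kb period) and is used wherever estimator accuracy
  is benchmarked, so that feature length is not the limiting factor for the
  short 5.8S/5S genes.
- **Depth noise**: per-base depth is negative binomial, independent across
  bases — mean `base_depth` (25×) at single-copy bases, `base_depth × CN` at
  unit-gene bases, with variance `m + m²/k`. Unit genes share one dispersion
  (k = 10). Each candidate exon draws its own dispersion log-uniformly from
  5–500, modelling mappability/GC differences in coverage evenness: only the
  high-k tail has a stable empirical mode, so the concordance filter
  genuinely selects a minority of evenly covered exons, mirroring the
  626-to-12 winnowing such filters perform on real libraries. (With one
  shared dispersion no exon can pass the mode criterion in 20 of 26
  lineages — the filter would reject everything.)
- **5S dropout**: a per-lineage fraction of units lacking 5S (uniform
  0–0.15) thins the 5S depth mean multiplicatively. Only depth is observable
  downstream, so dropout is modelled as a thinned mean rather than explicit
  per-unit presence.
- **High-copy decoys**: the first two exons are planted at 11× and 15×
  single-copy depth with top-of-range evenness, so they pass concordance and
  must be caught by the outlier screen.
- **Read counts**: Poisson totals whose expected ratio equals the truth
  proportion `100 × CN·L / (BG + CN·L)`; totals scale with ploidy, the
  ratio does not. Depth converts to reads at a fixed 150 bp read length.
- **Tree**: asexual tips are split into three clades and sexual tips into
  two, each grown by random sequential joining with exponential branch
  lengths (scale 0.08 within clades), then interleaved along a backbone
  (scale 0.4) so that no two asexual clades are sisters — asexuality reads
  as three separate origins, the confound structure the phylogenetic GEE
  must absorb.
- **Determinism**: all randomness flows from one seed through spawned
  per-lineage streams; identical config + seed yields byte-identical output
  files.

What the generator does *not* emulate: read-level artefacts (duplicates,
mapping quality, GC bias along a genome), sequence evolution of the genes,
linked depth fluctuations (noise is independent per base), partial-unit
truncation of the repeat array, and real exon length distributions. Passing
tests therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to alignment pathologies — those are upstream of
this package's contract (depth tables are assumed quality-filtered).

## Architecture inference

Hits are filtered at e-value ≤ 1e-50 and strand-normalised (BLAST encodes
minus-strand hits as start > end); coordinates stay 1-based inclusive
throughout the module. The anchor is the gene with the most occurrences on
the busiest scaffold (ties: longest gene). The period is the **median**
spacing between consecutive anchor starts — robust to one truncated terminal
unit, and exactly the unit length on clean arrays. Each anchor opens a
window of one period; hits inside it form that unit, so the consensus is
read in "anchor phase" (offsets modulo the period). Genes present in a
majority of anchored units enter the consensus, ordered by median offset,
with orientation by majority vote relative to the anchor's strand. Genes
falling outside every window belong to edge-truncated copies and are
reported as partial rather than voted. A unit is reported as lacking a
consensus gene (e.g. 5S) only when the gene's expected position falls
inside the observed hit span — absence at a scaffold edge is truncation,
not deviation. Single-anchor inputs return unit count 1 with the period
flagged undefined rather than guessed.

## Comparative statistics

Rank tests treat 5.8S as the representative of the co-amplifying 45S/histone
block (the genes are not independent — the Pearson matrix documents that)
and 5S separately. The Mann–Whitney U test uses the exact null (full
enumeration) when the combined sample is ≤ 12 without ties — C(12,6) = 924
assignments — and otherwise the normal approximation with tie and continuity
corrections. Kruskal–Wallis uses the chi-squared reference with tie
correction; an all-identical sample degenerates to p = 1 with a flag rather
than an error. Benjamini–Hochberg adjustment is applied within the family of
Kruskal–Wallis comparisons. (BH is *not* idempotent in general — re-adjusting
adjusted values can change them — so the tests assert the true invariants:
domination of raw values, order preservation, the cap at 1, and exact
step-up oracle equivalence.)

### The phylogenetic Poisson GEE

The model is `E[y] = exp(Xβ)`, `Var(y_i) = φ μ_i`, with a **fixed** working
correlation `R` derived from the tree: `R_ij` is the shared root-to-MRCA
path length scaled by the geometric mean of the two root-to-tip depths
(a Gram matrix, hence positive semi-definite; a 1e-8 ridge guards exactly
singular cases such as zero-length cherries). The quasi-score equations are
solved by Fisher scoring,

```
β ← β + (XᵀA½R⁻¹A½X)⁻¹ XᵀA½R⁻¹ (y−μ)/√μ ,   A = diag(μ),
```

applied to the (non-integer) copy-number estimates directly — GEE needs only
the mean–variance relationship. With `R = I` this is exactly Poisson
maximum-likelihood scoring, which the tests verify against an independent
GLM fit to 1e-6.

Two inference choices matter and were made deliberately:

- **Dispersion** is the generalized Pearson estimate `φ = rᵀR⁻¹r/(n−p)` on
  Pearson residuals, not the diagonal-only sum. With strongly correlated
  observations the diagonal estimator is so variable that Wald tests become
  anti-conservative (24% type-I at α = 0.05 in our null calibration versus
  5–6% for the generalized form); both coincide when `R = I`.
- **Standard errors** are model-based, `φ (XᵀA½R⁻¹A½X)⁻¹`: the whole cohort
  is a single correlated cluster, so the sandwich estimator is rank-1 and
  uninformative. It is still computed and exposed (`se_robust`) for
  diagnostics. Wald z uses the standard normal reference.

Calibration uses traits evolved by Brownian motion on the log scale along
the cohort trees (`brownian_copy_numbers`), whose tip covariance is exactly
the structure the working correlation assumes. The BM rate default (0.1 per
unit branch length) is set so the marginal within-mode spread matches the
roughly threefold range real cohorts show. Under the null (no mode effect,
modes clustered in clades) the phylogenetic fit rejects ~6% of the time at
α = 0.05 across 200 cohorts while the identity-correlation fit rejects
~40–50%; with a planted 10× effect the coefficient averages log 10 within a
few percent and p < 0.01 in ≥ 95% of replicates. These numbers are computed
by the test suite, not quoted.

One behavior worth knowing: when copy numbers are planted *independently* of
the tree (as the cohort generator's uniform draws are), closely related
lineages disagree far more than the working model expects; the generalized
dispersion absorbs that surprise and the GEE becomes strongly conservative.
That is the correct direction of failure for a correction whose purpose is
to avoid crediting clade effects to reproductive mode, but it means the GEE
p-value on such cohorts is much larger than the rank tests' — example 04
shows this honestly.

## Numerical and I/O conventions

- Depth tables are the `bedtools genomecov -d` dialect (feature, 1-based
  position, integer depth), with or without a header; gaps, duplicate
  positions and non-integer depths are hard errors, never silently filled.
- Annotation and hit coordinates are 1-based inclusive end to end;
  half-open conversions would happen only at I/O boundaries (none are
  currently needed).
- Pipeline outputs are written atomically (temp file + rename) with numeric
  precision fixed at 6 significant digits, making run manifests (config
  hash + output checksums) reproducible across runs.
- Tie-breaks are deterministic everywhere: smallest depth mode, first exon
  by coordinate, lexicographic gene order on equal offsets.

## Problem sizes

The default cohort is 26 lineages × (8 unit genes + 40 candidate exons of
0.3–2 kb), i.e. ~1.4 M simulated bases per cohort; the full test suite
simulates a handful of such cohorts plus 200 null cohorts for the GEE
calibration and completes in well under a minute on one CPU. These sizes
were chosen as the smallest at which the filter-chain combinatorics
(retention thresholds, outlier screen) and the GEE's clade structure are all
non-trivially exercised.

## Known limitations

- The depth mode of a wide count distribution is intrinsically unstable;
  the concordance filter consequently interacts with exon length and
  dispersion, and its pass rates on real libraries will depend on depth in
  ways the simulator only sketches.
- The outlier screen assumes at least half the retained exons are truly
  single copy (the reference level is their median).
- The architecture module assumes one dominant array on one scaffold; it
  reports, but does not model, nested or interleaved repeat families.
- The GEE's working correlation treats the tree as known and fixed;
  uncertainty in the phylogeny is not propagated.
- Wald inference uses the normal reference without small-sample degrees-of-
  freedom correction; with ~26 tips and few effective clades, p-values near
  a decision boundary deserve skepticism.
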