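"""Selection of the single-copy exon set used to normalise read depth.

The normaliser must be empirically single copy in (nearly) every lineage, or
the copy-number denominator is wrong everywhere.  The filter chain is:

1. ``pick_candidates`` -- the longest exon of each candidate gene, at least
   300 bp by default;
2. ``concordance_pass`` -- within a lineage, an exon's mean, median and mode
   depth must all lie within 10% of each other (multi-copy or partially
   duplicated exons show skewed, multi-modal depth and fail);
3. ``retain`` -- the exon must pass in a large majority of lineages
   (20 of 27 by default, rescaled by ceiling for other cohort sizes);
4. ``exclude_outliers`` -- exons whose cross-lineage median depth sits far
   above the rest (e.g. ~11x, ~15x) are evenly covered but high copy, and
   are removed with their exclusion factor reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: retention stringency: pass in at least 20 of 27 lineages
DEFAULT_RETENTION_RATIO = 20 / 27


@dataclass(frozen=True)
class ExonCandidate:
    gene_id: str
    exon_id: str
    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SelectionResult:
    """Outcome of the filter chain."""

    retained: tuple[str, ...]
    excluded_outliers: dict[str, float]  # exon id -> fold above reference median
    pass_matrix: pd.DataFrame  # exons x lineages, boolean
    total_length: int

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.excluded_outliers):
            raise ValueError("an exon cannot be both retained and excluded")


def pick_candidates(
    gene_models: pd.DataFrame, min_length: int = 300
) -> list[ExonCandidate]:
    """Longest exon per gene, dropping genes whose longest exon < ``min_length``.

    Expects columns gene_id, exon_id, scaffold, start, end (1-based
    inclusive).  Length ties within a gene resolve to the first exon in
    coordinate order.
    """
    required = {"gene_id", "exon_id", "scaffold", "start", "end"}
    missing = required - set(gene_models.columns)
    if missing:
        raise ValueError(f"gene-model table lacks columns: {sorted(missing)}")
    df = gene_models.copy()
    if (df["end"] < df["start"]).any():
        bad = df[df["end"] < df["start"]].iloc[0]
        raise ValueError(f"malformed span for exon {bad['exon_id']!r}: end < start")
    df["length"] = df["end"] - df["start"] + 1
    df = df.sort_values(["gene_id", "scaffold", "start"], kind="stable")
    candidates = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        best = grp.loc[grp["length"].idxmax()]  # idxmax: first max in order
        if best["length"] < min_length:
            continue
        candidates.append(
            ExonCandidate(
                gene_id=str(gene_id),
                exon_id=str(best["exon_id"]),
                scaffold=str(best["scaffold"]),
                start=int(best["start"]),
                end=int(best["end"]),
            )
        )
    return candidates


def concordance_pass(
    mean: float, median: float, mode: float, tolerance: float = 0.10
) -> bool:
    """True iff mean, median and mode are all within ``tolerance`` of each other.

    Interpreted as max/min <= 1 + tolerance over the three statistics.  If the
    smallest statistic is 0 the ratio is undefined; the exon passes only when
    all three are 0 (a uniformly uncovered exon is trivially concordant).
    """
    values = (mean, median, mode)
    if any(v < 0 for v in values):
        raise ValueError("coverage statistics must be non-negative")
    lo, hi = min(values), max(values)
    if lo == 0:
        return hi == 0
    return hi <= (1.0 + tolerance) * lo


def build_pass_matrix(
    summaries: pd.DataFrame, exon_ids: list[str], tolerance: float = 0.10
) -> pd.DataFrame:
    """Exon x lineage boolean matrix of concordance outcomes."""
    lineages = sorted(summaries["lineage"].unique())
    matrix = pd.DataFrame(False, index=exon_ids, columns=lineages)
    indexed = summaries.set_index(["feature", "lineage"])
    for exon in exon_ids:
        for lineage in lineages:
            try:
                row = indexed.loc[(exon, lineage)]
            except KeyError:
                continue
            matrix.loc[exon, lineage] = concordance_pass(
                row["mean"], row["median"], row["mode"], tolerance
            )
    return matrix


def retention_threshold(n_lineages: int, ratio: float = DEFAULT_RETENTION_RATIO) -> int:
    """Minimum pass count for a cohort of ``n_lineages`` (ceiling rescale)."""
    return math.ceil(ratio * n_lineages)


def retain(
    pass_matrix: pd.DataFrame, min_lineages: int | None = None
) -> tuple[str, ...]:
    """Exons passing concordance in at least ``min_lineages`` lineages."""
    n_lineages = pass_matrix.shape[1]
    if min_lineages is None:
        min_lineages = retention_threshold(n_lineages)
    if min_lineages > n_lineages:
        raise ValueError(
            f"min_lineages ({min_lineages}) exceeds cohort size ({n_lineages})"
        )
    counts = pass_matrix.sum(axis=1)
    return tuple(counts.index[counts >= min_lineages])


def exclude_outliers(
    median_by_exon: pd.Series, factor: float = 2.0
) -> tuple[tuple[str, ...], dict[str, float]]:
    """Drop exons whose cross-lineage median depth is far above the pack.

    ``median_by_exon`` maps exon id -> median (across lineages) of the exon's
    median depth.  The reference level is the median of those values; any exon
    above ``factor`` times it is excluded and reported with its fold factor.
    With fewer than three exons no exclusion is attempted (warning).
    """
    if factor <= 1.0:
        raise ValueError("outlier factor must exceed 1")
    if len(median_by_exon) < 3:
        warnings.warn(
            "fewer than 3 retained exons: outlier exclusion skipped", stacklevel=2
        )
        return tuple(median_by_exon.index), {}
    reference = float(median_by_exon.median())
    if reference <= 0:
        raise ValueError("reference median depth is zero; cannot screen outliers")
    folds = median_by_exon / reference
    excluded = {
        str(exon): float(f) for exon, f in folds.items() if f > factor
    }
    kept = tuple(str(e) for e in median_by_exon.index if e not in excluded)
    return kept, excluded


def select_single_copy(
    summaries: pd.DataFrame,
    candidates: list[ExonCandidate],
    tolerance: float = 0.10,
    min_lineages: int | None = None,
    outlier_factor: float = 2.0,
) -> SelectionResult:
    """Run the full filter chain and assemble a :class:`SelectionResult`."""
    exon_ids = [c.exon_id for c in candidates]
    lengths = {c.exon_id: c.length for c in candidates}
    matrix = build_pass_matrix(summaries, exon_ids, tolerance)
    surviving = retain(matrix, min_lineages)
    if not surviving:
        raise ValueError("no exon passed the concordance/retention filters")
    medians = (
        summaries[summaries["feature"].isin(surviving)]
        .groupby("feature")["median"]
        .median()
        .reindex(surviving)
    )
    kept, excluded = exclude_outliers(medians, outlier_factor)
    return SelectionResult(
        retained=kept,
        excluded_outliers=excluded,
        pass_matrix=matrix,
        total_length=int(sum(lengths[e] for e in kept)),
    )


def selection_report(result: SelectionResult) -> str:
    """Human-readable account of what was kept and why."""
    lines = [
        f"retained exons ({len(result.retained)}, {result.total_length} bp total):"
    ]
    for exon in result.retained:
        passes = int(result.pass_matrix.loc[exon].sum())
        lines.append(f"  {exon}\tpassed {passes}/{result.pass_matrix.shape[1]} lineages")
    if result.excluded_outliers:
        lines.append("excluded high-copy outliers:")
        for exon, fold in sorted(result.excluded_outliers.items()):
            lines.append(f"  {exon}\t~{fold:.1f}x above reference median depth")
    else:
        lines.append("excluded high-copy outliers: none")
    return "\n".join(lines) + "\n"
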