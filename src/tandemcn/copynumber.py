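"""Per-haploid copy number and genomic proportion of the tandem repeat.

The estimator is a median-depth ratio: for each lineage, the median per-base
depth of a repeat gene divided by the median depth over the pooled bases of
the retained single-copy exons.  Both numerator and denominator scale with
sequencing effort and with ploidy, so the ratio is per haploid genome by
construction.  Genomic proportion is the fraction of mapped reads attributable
to one (masked) repeat unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DepthTrack


@dataclass
class CopyNumberTable:
    """Lineage x gene matrix of per-haploid estimates plus per-lineage baselines."""

    values: pd.DataFrame  # index = lineage, columns = genes; NaN marks missing
    baseline: pd.Series  # index = lineage, single-copy median depth

    def __post_init__(self) -> None:
        numeric = self.values.to_numpy(dtype=float)
        if np.nanmin(numeric, initial=0.0) < 0:
            raise ValueError("copy-number estimates must be non-negative")
        if (self.baseline <= 0).any():
            raise ValueError("single-copy baseline must be positive for every lineage")

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis("lineage")
            .reset_index()
            .melt(id_vars="lineage", var_name="gene", value_name="copy_number")
        )
        long["baseline"] = long["lineage"].map(self.baseline)
        return long.sort_values(["lineage", "gene"]).reset_index(drop=True)


def single_copy_baseline(tracks: Sequence[DepthTrack]) -> float:
    """Median of the pooled per-base depths of all retained exons.

    Pooling (concatenation) rather than averaging per-exon medians weights the
    baseline by exon length, i.e. it is the median depth of the combined
    single-copy reference the estimator divides by.
    """
    if not tracks:
        raise ValueError("no exon tracks to pool")
    pooled = np.concatenate([t.depths for t in tracks])
    if pooled.size == 0:
        raise ValueError("empty depth pool")
    return float(np.median(pooled))


def per_haploid_cn(gene_track: DepthTrack, baseline: float) -> float:
    """Median depth of the gene divided by the single-copy baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return float(np.median(gene_track.depths)) / baseline


def genomic_proportion(reads_locus: int, reads_genome: int) -> float:
    """Percent of genome-mapped reads that map to the masked repeat locus."""
    if reads_genome <= 0:
        raise ValueError("reads mapped to genome must be positive")
    if reads_locus < 0 or reads_locus > reads_genome:
        raise ValueError("locus read count must lie in [0, reads_genome]")
    return 100.0 * reads_locus / reads_genome


def build_table(
    tracks_by_lineage: Mapping[str, Sequence[DepthTrack]],
    retained_exons: Sequence[str],
    unit_genes: Sequence[str],
    read_counts: pd.DataFrame | None = None,
) -> tuple[CopyNumberTable, pd.DataFrame | None]:
    """Assemble the full lineage x gene matrix (and proportions, if counts given).

    A gene with no track in a lineage becomes NaN -- an explicit missing
    marker, never zero, since zero is a meaningful estimate.  A lineage with
    no retained-exon coverage at all is an error: nothing can be normalised.
    """
    values: dict[str, dict[str, float]] = {}
    baselines: dict[str, float] = {}
    retained = set(retained_exons)
    for lineage, tracks in tracks_by_lineage.items():
        by_feature = {t.feature: t for t in tracks}
        exon_tracks = [by_feature[e] for e in retained_exons if e in by_feature]
        if not exon_tracks:
            raise ValueError(f"lineage {lineage!r} has no retained-exon coverage")
        baseline = single_copy_baseline(exon_tracks)
        if baseline <= 0:
            raise ValueError(f"lineage {lineage!r}: zero single-copy baseline")
        baselines[lineage] = baseline
        values[lineage] = {
            gene: (
                per_haploid_cn(by_feature[gene], baseline)
                if gene in by_feature
                else float("nan")
            )
            for gene in unit_genes
        }
    table = CopyNumberTable(
        values=pd.DataFrame.from_dict(values, orient="index")[list(unit_genes)],
        baseline=pd.Series(baselines, name="baseline"),
    )

    proportions = None
    if read_counts is not None:
        rows = []
        for row in read_counts.itertuples():
            rows.append(
                {
                    "lineage": row.lineage,
                    "reads_locus": int(row.reads_locus),
                    "reads_genome": int(row.reads_genome),
                    "proportion": genomic_proportion(
                        int(row.reads_locus), int(row.reads_genome)
                    ),
                }
            )
        proportions = pd.DataFrame(rows)
    return table, proportions


def write_table(table: CopyNumberTable, path: str | Path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> CopyNumberTable:
    long = pd.read_csv(path, sep="\t")
    values = long.pivot(
        index="lineage", columns="gene", values="copy_number"
    ).rename_axis(index=None, columns=None)
    baseline = long.groupby("lineage")["baseline"].first().rename_axis(None)
    return CopyNumberTable(values=values, baseline=baseline)
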