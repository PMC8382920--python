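"""Tandem-unit architecture inference from homology hits.

Given BLAST tabular hits of the eight query genes (18S, 5.8S, 28S, 5S, core
histones) against an assembly scaffold, reconstruct the repeat unit: which
gene anchors it, the unit period (bp), how many units are present, the
consensus gene order and per-gene orientation relative to the anchor, and
which individual units deviate from the consensus (e.g. units lacking 5S).

Coordinates are 1-based inclusive throughout, matching the BLAST dialect; a
subject start greater than the subject end encodes a minus-strand hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_EVALUE_CUTOFF = 1e-50


@dataclass
class RepeatUnitModel:
    """Consensus description of one tandem repeat unit."""

    scaffold: str
    anchor: str
    period: float | None  # bp between successive anchor copies; None if 1 unit
    n_units: int
    # consensus rows: gene, offset (bp from anchor start), strand ('+'/'-',
    # relative to the anchor's strand), support (units containing the gene)
    consensus: pd.DataFrame
    per_unit: pd.DataFrame  # unit_index, gene, start, end, strand
    partial_units: tuple[int, ...] = ()
    span: tuple[int, int] | None = None  # observed hit span on the scaffold

    @property
    def period_defined(self) -> bool:
        return self.period is not None

    def gene_order(self) -> tuple[str, ...]:
        return tuple(self.consensus["gene"])


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read outfmt-6 style BLAST tabular output (12 standard columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(
            f"expected >= 12 BLAST tabular columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    return df


def filter_hits(
    hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> pd.DataFrame:
    """Apply the e-value cutoff and normalise strands.

    Returns a frame with columns gene, scaffold, start, end, strand, evalue,
    pident where start <= end and strand records the original hit direction.
    """
    required = {"qseqid", "sseqid", "sstart", "send", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    if (hits[["sstart", "send"]] < 1).to_numpy().any():
        raise ValueError("subject coordinates must be positive (1-based)")
    kept = hits[hits["evalue"] <= evalue_cutoff]
    start = kept[["sstart", "send"]].min(axis=1)
    end = kept[["sstart", "send"]].max(axis=1)
    strand = np.where(kept["sstart"] <= kept["send"], "+", "-")
    return pd.DataFrame(
        {
            "gene": kept["qseqid"].astype(str).to_numpy(),
            "scaffold": kept["sseqid"].astype(str).to_numpy(),
            "start": start.astype(int).to_numpy(),
            "end": end.astype(int).to_numpy(),
            "strand": strand,
            "evalue": kept["evalue"].to_numpy(),
            "pident": (
                kept["pident"].to_numpy()
                if "pident" in kept
                else np.full(len(kept), np.nan)
            ),
        }
    ).reset_index(drop=True)


def _relative_strand(gene_strand: str, anchor_strand: str) -> str:
    return "+" if gene_strand == anchor_strand else "-"


def infer_unit_model(hits: pd.DataFrame) -> RepeatUnitModel:
    """Reconstruct the tandem unit from filtered, strand-normalised hits.

    The anchor is the gene with the most occurrences on the busiest scaffold
    (ties resolve to the longest gene, then lexicographically).  The period is
    the median spacing between consecutive anchor starts -- robust to one
    truncated terminal unit.  Each anchored window of one period defines a
    unit; genes falling outside every anchored window belong to truncated
    edge copies and are reported as partial, excluded from consensus voting.
    The consensus keeps genes present in a majority of units, ordered by their
    median offset from the anchor.
    """
    if hits.empty:
        raise ValueError("no hits to build a unit model from")
    scaffold = hits["scaffold"].value_counts().idxmax()
    scoped = hits[hits["scaffold"] == scaffold].copy()

    lengths = (scoped["end"] - scoped["start"] + 1).groupby(scoped["gene"]).median()
    counts = scoped["gene"].value_counts()
    order = sorted(
        counts.index,
        key=lambda g: (-counts[g], -lengths[g], g),
    )
    anchor = order[0]

    anchors = scoped[scoped["gene"] == anchor].sort_values("start")
    anchor_starts = anchors["start"].to_numpy()
    anchor_strands = anchors["strand"].to_numpy()
    n_anchors = len(anchor_starts)

    if n_anchors < 2:
        # single-unit input: no spacing to measure, period undefined
        start0 = int(anchor_starts[0])
        rows = []
        for row in scoped.sort_values("start").itertuples():
            rows.append(
                {
                    "unit_index": 0,
                    "gene": row.gene,
                    "start": row.start,
                    "end": row.end,
                    "strand": row.strand,
                }
            )
        per_unit = pd.DataFrame(rows)
        consensus = (
            per_unit.assign(
                offset=per_unit["start"] - start0,
                rel=[
                    _relative_strand(s, anchor_strands[0])
                    for s in per_unit["strand"]
                ],
            )
            .groupby("gene", as_index=False)
            .agg(offset=("offset", "median"), strand=("rel", "first"))
            .assign(support=1)
            .sort_values("offset", kind="stable")
            .reset_index(drop=True)
        )
        return RepeatUnitModel(
            scaffold=str(scaffold),
            anchor=anchor,
            period=None,
            n_units=1,
            consensus=consensus[["gene", "offset", "strand", "support"]],
            per_unit=per_unit,
            span=(int(scoped["start"].min()), int(scoped["end"].max())),
        )

    spacings = np.diff(anchor_starts)
    period = float(np.median(spacings))

    # assign every hit to the anchored window [anchor_i, anchor_i + period)
    unit_assign = np.searchsorted(anchor_starts, scoped["start"].to_numpy(), side="right") - 1
    in_window = (unit_assign >= 0) & (
        scoped["start"].to_numpy()
        < anchor_starts[np.clip(unit_assign, 0, n_anchors - 1)] + period
    )
    scoped = scoped.assign(unit_index=np.where(in_window, unit_assign, -1))
    per_unit = (
        scoped[scoped["unit_index"] >= 0]
        .sort_values(["unit_index", "start"])
        .reset_index(drop=True)[["unit_index", "gene", "start", "end", "strand"]]
    )
    orphan = scoped[scoped["unit_index"] < 0]

    votes = []
    for u, grp in per_unit.groupby("unit_index"):
        a0 = anchor_starts[int(u)]
        a_strand = anchor_strands[int(u)]
        for row in grp.itertuples():
            votes.append(
                {
                    "unit_index": int(u),
                    "gene": row.gene,
                    "offset": row.start - a0,
                    "rel": _relative_strand(row.strand, a_strand),
                }
            )
    votes_df = pd.DataFrame(votes)
    n_units = per_unit["unit_index"].nunique()
    majority = n_units / 2.0

    def strand_majority(rels: pd.Series) -> str:
        plus = (rels == "+").sum()
        return "+" if plus * 2 >= len(rels) else "-"

    agg = (
        votes_df.groupby("gene")
        .agg(
            offset=("offset", "median"),
            strand=("rel", strand_majority),
            support=("unit_index", "nunique"),
        )
        .reset_index()
    )
    consensus = (
        agg[agg["support"] > majority]
        .sort_values(["offset", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return RepeatUnitModel(
        scaffold=str(scaffold),
        anchor=anchor,
        period=period,
        n_units=int(n_units),
        consensus=consensus[["gene", "offset", "strand", "support"]],
        per_unit=per_unit,
        partial_units=(-1,) if len(orphan) else (),
        span=(int(scoped["start"].min()), int(scoped["end"].max())),
    )


def unit_deviations(model: RepeatUnitModel) -> pd.DataFrame:
    """Per-unit presence/absence of each consensus gene (e.g. missing 5S).

    A gene is only called absent from a unit when its expected position
    (anchor start plus consensus offset) lies inside the observed hit span;
    copies truncated by the scaffold edge are not deviations of the unit.
    """
    offsets = model.consensus.set_index("gene")["offset"]
    anchor_starts = (
        model.per_unit[model.per_unit["gene"] == model.anchor]
        .groupby("unit_index")["start"]
        .min()
    )
    rows = []
    for u, grp in model.per_unit.groupby("unit_index"):
        present = set(grp["gene"])
        a0 = anchor_starts.get(int(u), int(grp["start"].min()))
        for gene in model.gene_order():
            expected = a0 + offsets[gene]
            if model.span is not None and not (
                model.span[0] <= expected <= model.span[1]
            ):
                continue
            rows.append(
                {"unit_index": int(u), "gene": gene, "present": gene in present}
            )
    return pd.DataFrame(rows, columns=["unit_index", "gene", "present"])


def report(model: RepeatUnitModel) -> str:
    """Deterministic text schematic of the inferred unit."""
    lines = [
        f"scaffold: {model.scaffold}",
        f"anchor gene: {model.anchor}",
        (
            f"unit period: {model.period:.1f} bp"
            if model.period_defined
            else "unit period: undefined (single unit detected)"
        ),
        f"complete units detected: {model.n_units}",
    ]
    if not model.period_defined:
        lines.append("WARNING: only one unit detected; period cannot be estimated")
    lines.append("consensus unit (offsets from anchor start):")
    for row in model.consensus.itertuples():
        arrow = "-->" if row.strand == "+" else "<--"
        lines.append(
            f"  {row.gene:>5s} {arrow} at +{int(row.offset):>6d} bp"
            f"  (present in {row.support}/{model.n_units} units)"
        )
    dev = unit_deviations(model)
    missing = dev[~dev["present"]]
    if len(missing):
        for row in missing.itertuples():
            lines.append(f"  note: unit {row.unit_index} lacks {row.gene}")
    return "\n".join(lines) + "\n"
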