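"""Per-feature depth summaries (mean, median, mode) from per-base tables.

Input is the per-base depth dialect produced by ``bedtools genomecov -d`` (or
the simulator): one row per base, columns feature / 1-based position / integer
depth.  Tables are validated strictly -- depth must be integral, positions
contiguous from 1 -- because a silent gap would bias every downstream median.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class DepthTrack:
    """Ordered per-base depths for one feature in one lineage."""

    feature: str
    depths: np.ndarray
    lineage: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.size == 0:
            raise ValueError(f"empty depth track for feature {self.feature!r}")
        if not np.issubdtype(self.depths.dtype, np.integer):
            raise ValueError("depths must be integers")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return int(self.depths.size)


@dataclass(frozen=True)
class CoverageSummary:
    feature: str
    lineage: str
    mean: float
    median: float
    mode: int
    length: int


def read_depth_table(path: str | Path, lineage: str = "") -> list[DepthTrack]:
    """Parse a per-base depth TSV into one track per feature.

    Accepts a ``feature<TAB>position<TAB>depth`` header or the headerless
    three-column ``genomecov -d`` form.  Positions must be 1-based and
    contiguous within each feature; duplicates, gaps and non-integer depths
    are errors rather than warnings.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["feature", "position", "depth"], dtype=str
    )
    if len(df) and df.iloc[0]["position"] == "position":
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"empty depth table: {path}")
    try:
        positions = df["position"].astype(int)
        depths = df["depth"].astype(int)
    except ValueError as exc:
        raise ValueError(f"non-integer position or depth in {path}: {exc}") from None
    if (df["depth"].astype(float) != depths).any():
        raise ValueError(f"non-integer depth values in {path}")
    df = pd.DataFrame(
        {"feature": df["feature"], "position": positions, "depth": depths}
    )

    tracks = []
    for feature, grp in df.groupby("feature", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos[0] != 1:
            raise ValueError(f"feature {feature!r}: positions must start at 1")
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"feature {feature!r}: duplicated position")
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"feature {feature!r}: non-contiguous positions")
        tracks.append(
            DepthTrack(
                feature=str(feature),
                depths=grp["depth"].to_numpy(),
                lineage=lineage,
            )
        )
    return tracks


def tracks_from_frame(df: pd.DataFrame, lineage: str = "") -> list[DepthTrack]:
    """Build tracks from an in-memory (feature, position, depth) frame."""
    tracks = []
    for feature, grp in df.groupby("feature", sort=False):
        grp = grp.sort_values("position")
        tracks.append(
            DepthTrack(
                feature=str(feature),
                depths=grp["depth"].to_numpy().astype(int),
                lineage=lineage,
            )
        )
    return tracks


def mode_of(depths: Sequence[int] | np.ndarray) -> int:
    """Most frequent depth value; ties resolve to the smallest value."""
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("mode of empty sequence")
    values, counts = np.unique(arr, return_counts=True)
    # np.unique sorts values ascending, so argmax lands on the smallest tie
    return int(values[np.argmax(counts)])


def summarize(track: DepthTrack) -> CoverageSummary:
    """Mean / median (midpoint convention) / mode of one track."""
    d = track.depths
    return CoverageSummary(
        feature=track.feature,
        lineage=track.lineage,
        mean=float(np.mean(d)),
        median=float(np.median(d)),
        mode=mode_of(d),
        length=len(track),
    )


def summarize_all(tracks: Iterable[DepthTrack]) -> pd.DataFrame:
    """Summaries for many tracks as a tidy frame (one row per feature x lineage)."""
    rows = [summarize(t).__dict__ for t in tracks]
    if not rows:
        raise ValueError("no tracks to summarize")
    return pd.DataFrame(rows)
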