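"""Readers and writers for track and interval text formats.

Tracks go to bedGraph (chrom, start, end, value; missing bins omitted),
region and boundary sets to BED, loop anchors come from BEDPE, and contact
maps use the TSV triplet format handled in :mod:`pairhic.core`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import PairingRegionSet
from .core import BinTable, ScoreTrack
from .features import LoopList
from .insulation import BoundarySet


def write_bedgraph(track: ScoreTrack, path) -> None:
    bins = track.bin_table.bins
    keep = track.defined()
    df = bins[keep].copy()
    df["value"] = track.values[keep]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, bin_table: BinTable, kind: str = "generic") -> ScoreTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     float_precision="round_trip")
    values = np.full(bin_table.n_bins, np.nan)
    for row in df.itertuples():
        values[bin_table.bin_index(row.chrom, int(row.start))] = row.value
    return ScoreTrack(bin_table, values, kind=kind)


def write_regions_bed(regions: PairingRegionSet, path) -> None:
    """Regions as BED: name = label, score = loose fraction x 1000."""
    df = regions.intervals.copy()
    score = (df["loose_fraction"].fillna(0) * 1000).round().astype(int)
    out = pd.DataFrame({"chrom": df.chrom, "start": df.start, "end": df.end,
                        "name": df.label, "score": score})
    out.to_csv(path, sep="\t", header=False, index=False)


def write_boundaries_bed(boundaries: BoundarySet, bin_table: BinTable, path) -> None:
    """Boundaries as BED with the prominence in the score column."""
    bins = bin_table.bins
    out = pd.DataFrame({
        "chrom": bins.chrom.to_numpy()[boundaries.bins],
        "start": bins.start.to_numpy()[boundaries.bins],
        "end": bins.end.to_numpy()[boundaries.bins],
        "name": "boundary",
        "score": boundaries.prominences,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][:df.shape[1]]
    if df.shape[1] > 3:
        names = ["chrom", "start", "end", "state"] + list(names[4:])
    df.columns = names
    return df


def read_bedpe(path, window: int = 120_000) -> LoopList:
    """Loop anchors from BEDPE; the anchor position is each interval's start."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if (df.chrom1 != df.chrom2).any():
        raise ValueError("inter-chromosomal loop anchors are not supported")
    anchors = pd.DataFrame({"chrom": df.chrom1, "pos1": df.start1, "pos2": df.start2})
    return LoopList(anchors, window=window)


def write_scaling_tsv(curves, path) -> None:
    """One or more scaling curves as a tidy TSV."""
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "edge_lo": c.edges[:-1], "edge_hi": c.edges[1:], "s": c.s,
            "P": c.P, "n_pairs": c.n_pairs,
            "channel": c.channel, "region_class": c.region_class,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
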