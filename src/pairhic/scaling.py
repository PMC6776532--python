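"""Contact frequency versus genomic separation, P(s).

Curves are computed from binned maps: every intra-chromosomal bin pair
contributes its separation ``s = |start_i - start_j|`` to a geometric grid of
separation ranges (default 10 bp - 10 Mb, eight ranges per order of
magnitude, i.e. 48 ranges), and P(s) in a range is the total observed signal
divided by the number of contributing (unmasked) locus pairs.  The ratio
P_thom(s)/P_cis(s) measures how closely trans-homolog contacts track the cis
decay; restricting pairs to tightly or loosely paired regions exposes the
two-mode (shallow-then-steep) decay of domainized regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .core import ContactMap


def default_edges(lo: float = 10.0, hi: float = 1e7, per_decade: int = 8) -> np.ndarray:
    """Geometric separation-range edges, eight per order of magnitude."""
    n_ranges = int(round(np.log10(hi / lo) * per_decade))
    return lo * 10 ** (np.arange(n_ranges + 1) / per_decade)


@dataclass
class ScalingCurve:
    """Log-binned mean contact frequency per separation range."""

    edges: np.ndarray          # range edges, strictly increasing, length K+1
    P: np.ndarray              # mean contact frequency per range (NaN = missing)
    n_pairs: np.ndarray        # contributing locus pairs per range
    channel: str = ""
    region_class: str = "all"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.P = np.asarray(self.P, float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if len(self.P) != len(self.edges) - 1 or len(self.n_pairs) != len(self.P):
            raise ValueError("P and n_pairs must have one entry per range")

    @property
    def s(self) -> np.ndarray:
        """Representative separation per range: geometric mean of its edges."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def value_at(self, separation: float) -> float:
        k = int(np.searchsorted(self.edges, separation, side="right") - 1)
        if not (0 <= k < len(self.P)):
            raise ValueError(f"separation {separation} outside the edge span")
        return float(self.P[k])


def _accumulate(cmap: ContactMap, edges: np.ndarray, balanced: bool,
                region_id: np.ndarray | None = None):
    """Numerator/denominator sums per separation range.

    ``region_id`` (-1 = outside) restricts to pairs inside one region.
    """
    n_ranges = len(edges) - 1
    value_sum = np.zeros(n_ranges)
    pair_count = np.zeros(n_ranges, dtype=np.int64)
    valid = ~cmap.mask
    starts = cmap.bin_table.bins.start.to_numpy()
    w = cmap.weights

    coo = sp.triu(cmap.pixels, k=1).tocoo()
    i, j, data = coo.row, coo.col, coo.data.astype(float)
    slices = cmap.bin_table.chrom_slices()
    chrom_of = np.empty(cmap.bin_table.n_bins, dtype=np.int64)
    for c, sl in enumerate(slices.values()):
        chrom_of[sl] = c
    keep = chrom_of[i] == chrom_of[j]
    if region_id is not None:
        keep &= (region_id[i] >= 0) & (region_id[i] == region_id[j])
    i, j, data = i[keep], j[keep], data[keep]
    if balanced:
        data = data * w[i] * w[j]
    good = valid[i] & valid[j] & np.isfinite(data)
    sep = starts[j[good]] - starts[i[good]]
    k = np.searchsorted(edges, sep, side="right") - 1
    inside = (k >= 0) & (k < n_ranges) & (sep >= edges[0])
    np.add.at(value_sum, k[inside], data[good][inside])

    # denominator: all valid locus pairs per separation
    for sl in slices.values():
        v = valid[sl.start:sl.stop].copy()
        if region_id is not None:
            rid = region_id[sl.start:sl.stop]
            v &= rid >= 0
        nloc = len(v)
        for d in range(1, nloc):
            s_d = starts[sl.start + d] - starts[sl.start]
            k = int(np.searchsorted(edges, s_d, side="right") - 1)
            if k < 0 or k >= n_ranges or s_d < edges[0]:
                continue
            both = v[:-d] & v[d:]
            if region_id is not None:
                rid = region_id[sl.start:sl.stop]
                both &= rid[:-d] == rid[d:]
            pair_count[k] += int(np.count_nonzero(both))
    return value_sum, pair_count


def contact_frequency_curve(cmap: ContactMap, edges: np.ndarray | None = None,
                            balanced: bool | None = None) -> ScalingCurve:
    """P(s): observed signal per separation range over all contributing pairs.

    ``balanced=None`` uses balanced values when weights are present, raw
    counts otherwise.  Ranges with no contributing pairs are missing (NaN),
    not zero.
    """
    edges = default_edges() if edges is None else np.asarray(edges, float)
    if balanced is None:
        balanced = cmap.is_balanced
    if balanced and not cmap.is_balanced:
        raise ValueError("balanced P(s) requested on an unbalanced map")
    value_sum, pair_count = _accumulate(cmap, edges, balanced)
    with np.errstate(invalid="ignore"):
        P = np.where(pair_count > 0, value_sum / np.maximum(pair_count, 1), np.nan)
    return ScalingCurve(edges, P, pair_count, channel=cmap.channel)


def normalize_curve(curve: ScalingCurve, reference_curve: ScalingCurve | None = None,
                    reference_separation: float | None = None) -> ScalingCurve:
    """Divide a curve by a reference value, e.g. cis frequency at small s.

    By default the reference is the curve's own first non-missing range;
    passing a shared reference curve normalizes several channels jointly,
    which preserves their ratios at every separation.
    """
    ref = reference_curve if reference_curve is not None else curve
    if reference_separation is None:
        finite = np.flatnonzero(np.isfinite(ref.P))
        if finite.size == 0:
            raise ValueError("reference curve has no defined values")
        ref_value = float(ref.P[finite[0]])
    else:
        ref_value = ref.value_at(reference_separation)
    if not np.isfinite(ref_value) or ref_value == 0:
        raise ValueError("reference value is missing or zero")
    return replace(curve, P=curve.P / ref_value)


def ratio_curve(thom: ScalingCurve, cis: ScalingCurve) -> ScalingCurve:
    """Element-wise P_thom(s)/P_cis(s); missing where either is missing."""
    if not np.array_equal(thom.edges, cis.edges):
        raise ValueError("curves must share separation edges")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = thom.P / cis.P
    ratio[~np.isfinite(ratio)] = np.nan
    return ScalingCurve(thom.edges, ratio, np.minimum(thom.n_pairs, cis.n_pairs),
                        channel=f"{thom.channel}/{cis.channel}",
                        region_class=thom.region_class)


def region_restricted_curves(cmap: ContactMap, regions, edges: np.ndarray | None = None,
                             balanced: bool | None = None) -> dict[str, ScalingCurve]:
    """One P(s) per region class, using only pairs within the same region.

    ``regions`` provides ``intervals`` — a DataFrame with chrom/start/end and
    a ``label`` column (tight/loose).  Cross-region pairs contribute to no
    curve.
    """
    edges = default_edges() if edges is None else np.asarray(edges, float)
    if balanced is None:
        balanced = cmap.is_balanced
    bt = cmap.bin_table
    intervals = regions.intervals if hasattr(regions, "intervals") else regions
    out: dict[str, ScalingCurve] = {}
    for label in sorted(intervals["label"].unique()):
        sub = intervals[intervals["label"] == label]
        region_id = np.full(bt.n_bins, -1, dtype=np.int64)
        for rid, row in enumerate(sub.itertuples()):
            if row.end <= row.start:
                continue
            lo = bt.bin_index(row.chrom, row.start)
            hi = bt.bin_index(row.chrom, row.end - 1) + 1
            region_id[lo:hi] = rid
        if not np.any(region_id >= 0):
            warnings.warn(f"region class {label!r} covers no bins; curve missing")
            out[label] = ScalingCurve(edges, np.full(len(edges) - 1, np.nan),
                                      np.zeros(len(edges) - 1, dtype=np.int64),
                                      channel=cmap.channel, region_class=label)
            continue
        value_sum, pair_count = _accumulate(cmap, edges, balanced, region_id)
        with np.errstate(invalid="ignore"):
            P = np.where(pair_count > 0, value_sum / np.maximum(pair_count, 1), np.nan)
        out[label] = ScalingCurve(edges, P, pair_count, channel=cmap.channel,
                                  region_class=label)
    return out


def log_slope(curve: ScalingCurve) -> np.ndarray:
    """Per-range d log10 P / d log10 s by centered differences.

    Missing (NaN) where either neighbor is missing; endpoints are missing.
    """
    logs = np.log10(curve.s)
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.log10(curve.P)
    slope = np.full_like(logp, np.nan)
    num = logp[2:] - logp[:-2]
    den = logs[2:] - logs[:-2]
    slope[1:-1] = num / den
    return slope
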