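"""Diamond insulation scores and prominence-filtered boundary detection.

The insulation score of bin i sums the balanced contacts formed *across* i
by bin pairs up to w bins away on either side (a w x w diamond strictly
straddling i), log2-normalized by the genome-wide median.  Domain boundaries
are local minima of this track; genuine boundaries are separated from noise
by their prominence — the smaller of the rises to the flanking maxima found
by an alternating-extrema scan.  Boundaries sitting next to bins masked
during balancing are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ContactMap, ScoreTrack


def insulation_score(cmap: ContactMap, w: int = 5) -> ScoreTrack:
    """log2 median-normalized diamond insulation track.

    raw(i) sums balanced values over pairs (a, b) with a in [i-w, i-1] and
    b in [i+1, i+w].  The track is missing within w bins of chromosome ends
    and wherever any bin of the diamond is masked.  Median normalization
    makes the track invariant to a uniform rescaling of the map.  The
    default w = 5 suits a 4 kb grid (a 20 kb flank).
    """
    if not cmap.is_balanced:
        raise ValueError("insulation_score requires a balanced map")
    if w < 1:
        raise ValueError("flank width must be >= 1")
    n = cmap.bin_table.n_bins
    raw = np.full(n, np.nan)
    mask = cmap.mask
    for chrom, sl in cmap.bin_table.chrom_slices().items():
        m = sl.stop - sl.start
        if m < 2 * w + 1:
            warnings.warn(f"{chrom} shorter than the insulation window; skipped")
            continue
        D = cmap.to_dense(chrom, balanced=True)
        cm = mask[sl]
        if cm.all():
            warnings.warn(f"{chrom} fully masked; skipped")
            continue
        for i in range(w, m - w):
            if cm[i - w:i + w + 1].any():
                continue
            raw[sl.start + i] = D[i - w:i, i + 1:i + w + 1].sum()
    good = np.isfinite(raw)
    if not good.any():
        raise ValueError("no bin has a defined insulation value")
    med = np.median(raw[good])
    if med <= 0:
        raise ValueError("non-positive median insulation; map too sparse")
    values = np.full(n, np.nan)
    with np.errstate(divide="ignore"):
        values[good] = np.log2(raw[good] / med)
    values[np.isneginf(values)] = np.nan
    return ScoreTrack(cmap.bin_table, values, kind="insulation", window=w)


@dataclass
class BoundarySet:
    """Insulation-minimum boundaries that passed the prominence cutoff."""

    bins: np.ndarray            # global bin indices, strictly increasing
    prominences: np.ndarray     # one per boundary, all >= cutoff
    cutoff: float
    channel: str = ""

    def __len__(self) -> int:
        return len(self.bins)


def _alternating_extrema(y: np.ndarray, idx: np.ndarray, delta: float):
    """Minima and maxima by the alternating-extrema (peak-detection) scan.

    An extremum is registered once the series has moved away from the
    running candidate by more than ``delta``; detected minima and maxima
    strictly alternate.  Returns (minima, maxima) as positions into ``idx``.
    """
    minima, maxima = [], []
    look_for_max = None
    mn = mx = y[0]
    mn_pos = mx_pos = idx[0]
    for pos, v in zip(idx[1:], y[1:]):
        if v > mx:
            mx, mx_pos = v, pos
        if v < mn:
            mn, mn_pos = v, pos
        if look_for_max is None:
            if v >= mn + delta:
                look_for_max = True
                minima.append(mn_pos)
                mx, mx_pos = v, pos
            elif v <= mx - delta:
                look_for_max = False
                maxima.append(mx_pos)
                mn, mn_pos = v, pos
        elif look_for_max:
            if v <= mx - delta:
                maxima.append(mx_pos)
                mn, mn_pos = v, pos
                look_for_max = False
        else:
            if v >= mn + delta:
                minima.append(mn_pos)
                mx, mx_pos = v, pos
                look_for_max = True
    return minima, maxima


def find_boundaries(track: ScoreTrack, min_prominence: float = 0.3,
                    channel: str = "", mask: np.ndarray | None = None) -> BoundarySet:
    """Prominent insulation minima, excluding those next to masked bins.

    The prominence of a minimum is the smaller of the rises to its flanking
    detected maxima (track ends act as maxima for edge minima).  The
    detection delta of the alternating-extrema scan is min_prominence / 2.
    Customary cutoffs: 0.3 for haplotype-resolved channels, 0.1 for maps on
    the pooled reference.  A monotone track yields an empty set.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    delta = min_prominence / 2
    keep_bins: list[int] = []
    keep_prom: list[float] = []
    values = track.values
    for sl in track.bin_table.chrom_slices().values():
        seg = values[sl]
        defined = np.isfinite(seg)
        if defined.sum() < 3:
            continue
        idx = np.flatnonzero(defined) + sl.start
        y = seg[defined]
        minima, maxima = _alternating_extrema(y, idx, delta)
        pos_of = {int(p): k for k, p in enumerate(idx)}
        for mpos in minima:
            k = pos_of[int(mpos)]
            left = [p for p in maxima if p < mpos]
            right = [p for p in maxima if p > mpos]
            lval = y[pos_of[int(left[-1])]] if left else y[:k + 1].max()
            rval = y[pos_of[int(right[0])]] if right else y[k:].max()
            prom = min(lval, rval) - y[k]
            if prom >= min_prominence:
                keep_bins.append(int(mpos))
                keep_prom.append(float(prom))

    bins = np.array(sorted(keep_bins), dtype=int)
    proms = np.array([p for _, p in sorted(zip(keep_bins, keep_prom))])
    if mask is not None and bins.size:
        n = len(mask)
        bad = np.array([mask[b] or (b > 0 and mask[b - 1])
                        or (b < n - 1 and mask[b + 1]) for b in bins])
        bins, proms = bins[~bad], proms[~bad]
    return BoundarySet(bins, proms, min_prominence, channel)


def boundary_overlap(a: BoundarySet, b: BoundarySet, tolerance: int = 4):
    """Fraction of a's boundaries with a match in b within ``tolerance`` bins.

    Matching is greedy nearest-first and one-to-one (a boundary of b is used
    at most once).  The default tolerance of 4 bins (16 kb on a 4 kb grid)
    absorbs the positional drift between stochastic maps.  Returns the pair
    (fraction of a matched in b, fraction of b matched in a); a fraction is
    NaN when the corresponding set is empty.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    pairs = []
    for ia, pa in enumerate(a.bins):
        for ib, pb in enumerate(b.bins):
            d = abs(int(pa) - int(pb))
            if d <= tolerance:
                pairs.append((d, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        matched += 1
    frac_a = matched / len(a.bins) if len(a.bins) else np.nan
    frac_b = matched / len(b.bins) if len(b.bins) else np.nan
    if len(a.bins) == 0 or len(b.bins) == 0:
        warnings.warn("empty boundary set; overlap fraction undefined")
    return frac_a, frac_b


def interval_overlap_fraction(boundaries: BoundarySet, intervals,
                              bin_table) -> float:
    """Fraction of boundary bins intersecting at least one interval.

    ``intervals`` is a DataFrame with chrom/start/end (e.g. ChIP-seq peaks);
    a boundary overlaps when its bin's [start, end) intersects any interval.
    NaN for an empty boundary set.
    """
    if len(boundaries) == 0:
        warnings.warn("empty boundary set")
        return float("nan")
    bins = bin_table.bins
    hits = 0
    for bidx in boundaries.bins:
        chrom = bins.chrom.iloc[bidx]
        lo, hi = bins.start.iloc[bidx], bins.end.iloc[bidx]
        sub = intervals[intervals["chrom"] == chrom]
        if ((sub["start"] < hi) & (sub["end"] > lo)).any():
            hits += 1
    return hits / len(boundaries)
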