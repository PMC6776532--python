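"""Tight/loose pairing classification from the pairing-score distribution.

The genome-wide PS distribution shows a high peak (tightly paired bins) with
a tail toward low values (loosely paired bins).  A two-component Gaussian
mixture separates the two; the density intersection between the component
means is the classification threshold.  Bins are labeled by thresholding
PS, and inter-boundary regions are labeled by their fraction of loose bins
(a quarter of loose bins suffices to call a region loose, since PS dips are
gradual near boundaries), then merged across boundaries whose own bin
carries the same label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .core import BinTable, ScoreTrack


@dataclass
class GaussianMixtureFit:
    """Two-Gaussian fit of a PS sample and its density-intersection threshold.

    Components are ordered so ``mean_loose < mean_tight``.  ``threshold`` is
    the PS value where the two weighted component densities are equal,
    restricted to the interval between the means.  ``reliable`` is False when
    the components collapsed onto each other (effectively one Gaussian), in
    which case the threshold is not a meaningful class separator.
    """

    weight_loose: float
    weight_tight: float
    mean_loose: float
    mean_tight: float
    sd_loose: float
    sd_tight: float
    clip_floor: float
    threshold: float
    log_likelihood: float
    reliable: bool = True


def fit_two_gaussians(ps_values: np.ndarray, clip_floor: float = -3.0,
                      tol: float = 1e-8, max_iter: int = 1000) -> GaussianMixtureFit:
    """Fit a two-component Gaussian mixture to a PS sample by EM.

    Values below ``clip_floor`` (default -3, in log2 units) are winsorized to
    the floor before fitting, which stabilizes EM against the extreme loose
    tail while preserving its mass.  Initialization is deterministic: means
    at the 25th/75th percentiles, equal weights, both sds at half the sample
    sd.  A degenerate fit (vanishing component variance) is retried with a
    variance floor.
    """
    x = np.asarray(ps_values, float)
    x = x[np.isfinite(x)]
    if x.size < 500:
        raise ValueError(f"need >= 500 finite PS values, got {x.size}")
    x = np.maximum(x, clip_floor)[:, None]

    means0 = np.percentile(x, [25, 75])[:, None]
    sd0 = x.std() / 2
    kwargs = dict(
        n_components=2, covariance_type="spherical", tol=tol, max_iter=max_iter,
        weights_init=np.array([0.5, 0.5]), means_init=means0,
        precisions_init=np.array([1 / sd0**2, 1 / sd0**2]),
    )
    try:
        gm = GaussianMixture(reg_covar=0.0, **kwargs).fit(x)
        degenerate = bool(np.any(gm.covariances_ < 1e-12))
    except ValueError:           # a component collapsed onto a point mass
        degenerate = True
    if degenerate:
        gm = GaussianMixture(reg_covar=1e-4, **kwargs).fit(x)
        if np.any(gm.covariances_ < 1e-10):
            raise RuntimeError("EM degenerate even with a variance floor")

    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_[order])
    fit = GaussianMixtureFit(
        weight_loose=float(w[0]), weight_tight=float(w[1]),
        mean_loose=float(mu[0]), mean_tight=float(mu[1]),
        sd_loose=float(sd[0]), sd_tight=float(sd[1]),
        clip_floor=clip_floor, threshold=np.nan,
        log_likelihood=float(gm.score(x) * x.size),
    )
    if mu[1] - mu[0] < 0.5 * sd.max():
        # components overlap so heavily the sample is effectively one
        # Gaussian; the crossing is not a meaningful class separator
        fit.reliable = False
        try:
            fit.threshold = intersection_threshold(fit)
        except ValueError:
            fit.threshold = float(mu.mean())
        return fit
    fit.threshold = intersection_threshold(fit)
    return fit


def intersection_threshold(fit: GaussianMixtureFit) -> float:
    """PS value where the two weighted Gaussian densities cross.

    Solves w1*phi(x; mu1, sd1) = w2*phi(x; mu2, sd2) — a quadratic in x via
    log densities — and returns the root strictly between the component
    means.  With equal weights and sds this is exactly the midpoint of the
    means.
    """
    w1, w2 = fit.weight_loose, fit.weight_tight
    m1, m2 = fit.mean_loose, fit.mean_tight
    s1, s2 = fit.sd_loose, fit.sd_tight
    if min(w1, w2) <= 0:
        raise ValueError("both mixture weights must be positive")
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log(w1 / s1) - np.log(w2 / s2))
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            raise ValueError("densities never cross (identical components)")
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise ValueError(
                f"no density crossing between means (fit: {fit})")
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                          (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise ValueError(
            f"no density crossing in ({m1:.4g}, {m2:.4g}); fit: {fit}")
    return float(inside[0])


# ---------------------------------------------------------------------------
# Bin and region labels
# ---------------------------------------------------------------------------

LOOSE, TIGHT, MISSING = "loose", "tight", "missing"


def classify_bins(ps: ScoreTrack, threshold: float) -> np.ndarray:
    """Per-bin labels: PS < threshold -> loose, PS >= threshold -> tight.

    Bins without a PS value are 'missing'.  The inequality is strict for
    loose, so a bin exactly at the threshold is tight.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.full(ps.bin_table.n_bins, MISSING, dtype=object)
    defined = ps.defined()
    labels[defined & (ps.values < threshold)] = LOOSE
    labels[defined & (ps.values >= threshold)] = TIGHT
    return labels


@dataclass
class PairingRegionSet:
    """Boundary-delimited intervals labeled tight or loose.

    ``intervals`` has columns chrom, start, end (0-based half-open), label,
    loose_fraction; intervals are sorted, non-overlapping and tile the
    analyzed bins.
    """

    intervals: pd.DataFrame
    loose_cutoff: float = 0.25

    def lengths(self) -> np.ndarray:
        return (self.intervals.end - self.intervals.start).to_numpy()


def _region_label(bin_labels: np.ndarray, lo: int, hi: int, cutoff: float):
    seg = bin_labels[lo:hi]
    informative = seg != MISSING
    if not informative.any():
        return MISSING, np.nan
    frac = float((seg == LOOSE).sum() / informative.sum())
    return (LOOSE if frac >= cutoff else TIGHT), frac


def classify_regions(bin_labels: np.ndarray, boundaries, bin_table: BinTable,
                     loose_cutoff: float = 0.25) -> PairingRegionSet:
    """Label inter-boundary regions tight/loose and merge across like boundaries.

    The genome is split at the given boundaries (chromosome ends are implicit
    boundaries).  A region is loose when its fraction of loose bins (missing
    bins excluded) reaches ``loose_cutoff``; spurious splits are healed by
    merging adjacent same-label regions whenever the boundary bin between
    them carries that same bin-level label, repeated to a fixed point.
    Regions whose bins are all missing stay 'missing' and never merge.
    """
    bidx = np.asarray(getattr(boundaries, "bins", boundaries), dtype=int)
    slices = bin_table.chrom_slices()
    pieces = []
    for chrom, sl in slices.items():
        inner = np.sort(bidx[(bidx > sl.start) & (bidx < sl.stop)])
        edges = np.concatenate([[sl.start], inner, [sl.stop]])
        segs = [[int(edges[k]), int(edges[k + 1])] for k in range(len(edges) - 1)]

        changed = True
        while changed:
            changed = False
            merged = [segs[0]]
            for seg in segs[1:]:
                prev = merged[-1]
                lab_prev, _ = _region_label(bin_labels, prev[0], prev[1], loose_cutoff)
                lab_cur, _ = _region_label(bin_labels, seg[0], seg[1], loose_cutoff)
                bbin = bin_labels[seg[0]]  # boundary bin between prev and seg
                if (lab_prev == lab_cur and lab_prev != MISSING and bbin == lab_prev):
                    prev[1] = seg[1]
                    changed = True
                else:
                    merged.append(seg)
            segs = merged

        starts = bin_table.bins.start.to_numpy()
        ends = bin_table.bins.end.to_numpy()
        for lo, hi in segs:
            label, frac = _region_label(bin_labels, lo, hi, loose_cutoff)
            pieces.append((chrom, int(starts[lo]), int(ends[hi - 1]), label, frac))
    df = pd.DataFrame(pieces, columns=["chrom", "start", "end", "label", "loose_fraction"])
    return PairingRegionSet(df, loose_cutoff)


def select_regions_by_size(regions: PairingRegionSet, lo: int, hi: int) -> PairingRegionSet:
    """Keep regions with lo <= length < hi (base pairs).

    The standard size classes for comparing region architecture are
    100-200 kb and 200-400 kb.
    """
    if not lo < hi:
        raise ValueError("size class requires lo < hi")
    lengths = regions.intervals.end - regions.intervals.start
    keep = (lengths >= lo) & (lengths < hi)
    return PairingRegionSet(regions.intervals[keep].reset_index(drop=True),
                            regions.loose_cutoff)


SIZE_CLASSES = {"100-200kb": (100_000, 200_000), "200-400kb": (200_000, 400_000)}
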