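"""Compartment eigenvectors, PS-annotation associations, loops, disomy.

These estimators relate the pairing-score track to the rest of the nuclear
organization readouts: A/B compartment eigenvectors of the observed/expected
map, Spearman correlations and quadrant fractions against eigenvector or
expression tracks, Mood's median test of PS across chromatin states, summed
balanced contact frequency around loop anchors, and the closed-form partial
disomy estimate from homolog coverage ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla
from scipy import stats

from .core import BinTable, ContactMap, ScoreTrack, observed_over_expected


# ---------------------------------------------------------------------------
# Compartment eigenvectors
# ---------------------------------------------------------------------------

def compartment_eigenvector(cmap: ContactMap, gene_count_track: ScoreTrack,
                            n_eigs: int = 3) -> tuple[ScoreTrack, dict[str, np.ndarray]]:
    """Leading eigenvector of (O/E - 1) that best tracks gene density.

    Per chromosome, the observed/expected matrix minus one (masked rows
    removed) is decomposed; each of the first ``n_eigs`` eigenvectors is
    scaled by sqrt(|eigenvalue|), and the one with the highest absolute
    Pearson correlation with the gene-count track is reported, sign-oriented
    so that the correlation is positive (A compartments, being gene rich,
    come out positive).  Returns the eigenvector track and the per-chromosome
    eigenvalues.
    """
    oe = observed_over_expected(cmap)
    n = cmap.bin_table.n_bins
    ev = np.full(n, np.nan)
    eigvals: dict[str, np.ndarray] = {}
    for chrom, sl in cmap.bin_table.chrom_slices().items():
        if chrom not in oe:
            continue
        A = oe[chrom] - 1.0
        valid = ~cmap.mask[sl]
        sub = np.nan_to_num(A[np.ix_(valid, valid)], nan=0.0)
        k = min(n_eigs, sub.shape[0] - 2)
        if k < 1:
            warnings.warn(f"{chrom}: too few unmasked bins for eigendecomposition")
            continue
        v0 = np.full(sub.shape[0], 1.0 / np.sqrt(sub.shape[0]))
        vals, vecs = spla.eigsh(sub, k=k, which="LM", v0=v0)
        order = np.argsort(-np.abs(vals))
        vals, vecs = vals[order], vecs[:, order]
        gene = gene_count_track.values[sl][valid]
        best, best_corr = 0, -np.inf
        for t in range(k):
            v = vecs[:, t] * np.sqrt(abs(vals[t]))
            if np.std(v) == 0 or np.std(gene) == 0:
                continue
            c = np.corrcoef(v, gene)[0, 1]
            if abs(c) > abs(best_corr) or best_corr == -np.inf:
                best, best_corr = t, c
        chosen = vecs[:, best] * np.sqrt(abs(vals[best]))
        if best_corr < 0:
            chosen = -chosen
        out = np.full(sl.stop - sl.start, np.nan)
        out[valid] = chosen
        ev[sl] = out
        eigvals[chrom] = vals
    return ScoreTrack(cmap.bin_table, ev, kind="eigenvector"), eigvals


# ---------------------------------------------------------------------------
# Track associations
# ---------------------------------------------------------------------------

def track_correlation(a: ScoreTrack, b: ScoreTrack) -> tuple[float, float]:
    """Spearman rank correlation over bins where both tracks are defined."""
    both = a.defined() & b.defined()
    if both.sum() < 10:
        raise ValueError("need >= 10 jointly defined bins")
    x, y = a.values[both], b.values[both]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant track; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def quadrant_fractions(ps: ScoreTrack, ps_threshold: float,
                       other: ScoreTrack, other_threshold: float | None = None
                       ) -> dict[str, float]:
    """Genome fractions in the four (tight/loose) x (high/low) quadrants.

    ``other`` is typically the compartment eigenvector (high = A-type) or an
    expression track (high = expressed); its threshold defaults to the
    median over jointly defined bins.  Fractions are over jointly defined
    bins and sum to 1.
    """
    both = ps.defined() & other.defined()
    if not both.any():
        raise ValueError("no bins with both tracks defined")
    p = ps.values[both]
    o = other.values[both]
    if other_threshold is None:
        other_threshold = float(np.median(o))
    tight = p >= ps_threshold
    high = o >= other_threshold
    n = both.sum()
    return {
        "tight_high": float((tight & high).sum() / n),
        "tight_low": float((tight & ~high).sum() / n),
        "loose_high": float((~tight & high).sum() / n),
        "loose_low": float((~tight & ~high).sum() / n),
    }


def chromatin_state_association(ps: ScoreTrack, states: pd.DataFrame,
                                reference_state: str, min_bins: int = 10
                                ) -> pd.DataFrame:
    """PS distributions per chromatin state with Mood's median test.

    ``states`` is a BED-like DataFrame (chrom, start, end, state).  Each bin
    takes the state covering its start.  For every non-reference state a
    Mood's median test against the reference is run: a 2x2 chi-square of
    counts above/below the pooled median (no continuity correction).  States
    with fewer than ``min_bins`` bins are dropped with a warning.
    """
    if (states["state"] == reference_state).sum() == 0:
        raise ValueError(f"reference state {reference_state!r} absent")
    bins = ps.bin_table.bins
    bin_state = np.full(ps.bin_table.n_bins, "", dtype=object)
    for row in states.itertuples():
        sel = ((bins.chrom == row.chrom) & (bins.start >= row.start)
               & (bins.start < row.end))
        bin_state[sel.to_numpy()] = row.state
    defined = ps.defined() & (bin_state != "")
    samples = {s: ps.values[defined & (bin_state == s)]
               for s in pd.unique(states["state"])}
    for s in list(samples):
        if samples[s].size < min_bins:
            warnings.warn(f"state {s!r} has {samples[s].size} bins (< {min_bins}); excluded")
            del samples[s]
    if reference_state not in samples:
        raise ValueError(f"reference state {reference_state!r} has too few bins")
    ref = samples[reference_state]
    rows = []
    for s, vals in samples.items():
        if s == reference_state:
            rows.append((s, vals.size, float(np.median(vals)), np.nan, np.nan))
            continue
        stat, p, _, _ = stats.median_test(ref, vals, ties="below", correction=False)
        rows.append((s, vals.size, float(np.median(vals)), float(stat), float(p)))
    return pd.DataFrame(rows, columns=["state", "n_bins", "median_ps",
                                       "chi_square", "p_value"])


# ---------------------------------------------------------------------------
# Loop quantitation
# ---------------------------------------------------------------------------

@dataclass
class LoopList:
    """Loop anchors (chrom, pos1, pos2) and the quantitation window in bp."""

    anchors: pd.DataFrame       # columns: chrom, pos1, pos2
    window: int = 120_000


def loop_quantitation(cmap: ContactMap, loops: LoopList) -> pd.DataFrame:
    """Summed balanced contact frequency in a window around each loop.

    The window (default 120 kb x 120 kb, i.e. 30 x 30 bins at 4 kb) is
    centered on the anchor pixel; masked pixels contribute zero and windows
    truncated at chromosome ends are flagged.
    """
    if not cmap.is_balanced:
        raise ValueError("loop_quantitation requires a balanced map")
    bt = cmap.bin_table
    if loops.window % bt.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    nb = loops.window // bt.bin_size
    half_lo = nb // 2
    half_hi = nb - half_lo
    rows = []
    slices = bt.chrom_slices()
    S = cmap.symmetric()
    for k, row in enumerate(loops.anchors.itertuples()):
        try:
            bi = bt.bin_index(row.chrom, int(row.pos1))
            bj = bt.bin_index(row.chrom, int(row.pos2))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"loop record {k} off the assembly: {exc}") from exc
        sl = slices[row.chrom]
        lo_i, hi_i = max(sl.start, bi - half_lo), min(sl.stop, bi + half_hi)
        lo_j, hi_j = max(sl.start, bj - half_lo), min(sl.stop, bj + half_hi)
        truncated = (hi_i - lo_i != nb) or (hi_j - lo_j != nb)
        dense = np.asarray(S[lo_i:hi_i, lo_j:hi_j].todense(), dtype=float)
        w = cmap.weights
        bal = dense * np.outer(w[lo_i:hi_i], w[lo_j:hi_j])
        total = float(np.nansum(bal))
        rows.append((row.chrom, int(row.pos1), int(row.pos2), total, truncated))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2",
                                       "balanced_sum", "truncated"])


# ---------------------------------------------------------------------------
# Disomy
# ---------------------------------------------------------------------------

@dataclass
class DisomyEstimate:
    """Partial-disomy estimate from the homolog coverage ratio.

    A disomy of one homolog in a fraction x of cells raises its coverage by
    r = (1 + x)/(1 - x); inverting, x = (r - 1)/(r + 1).
    """

    ratio: float                # higher-coverage homolog over lower, r >= 1
    fraction: float             # disomic cell fraction x in [0, 1)
    swapped: bool = False       # homolog roles were exchanged to make r >= 1


def disomy_fraction(coverage_high: np.ndarray, coverage_low: np.ndarray) -> DisomyEstimate:
    """Estimate the disomic cell fraction over a region.

    ``coverage_high``/``coverage_low`` are per-bin coverages of the two
    homologs over the region of interest; if the first is actually the lower
    one, the roles are swapped and recorded.
    """
    hi = np.asarray(coverage_high, float)
    lo = np.asarray(coverage_low, float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("region must be non-empty")
    if np.any(hi <= 0) or np.any(lo <= 0):
        raise ValueError("coverages must be positive over the region")
    r = hi.mean() / lo.mean()
    swapped = r < 1
    if swapped:
        r = 1 / r
    x = (r - 1) / (r + 1)
    return DisomyEstimate(float(r), float(x), swapped)


def disomy_ratio_from_fraction(x: float) -> float:
    """Closed-form inverse: coverage ratio r implied by disomic fraction x."""
    if not 0 <= x < 1:
        raise ValueError("fraction must be in [0, 1)")
    return (1 + x) / (1 - x)
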