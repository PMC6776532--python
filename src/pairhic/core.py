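"""Core data model for binned haplotype-tagged contact maps.

A diploid Hi-C experiment with phased SNVs yields several *channels* of
contacts on a single reference bin grid: reads where both ends map to the
maternal copy (``cis_maternal``), to the paternal copy (``cis_paternal``),
to different homologs of the same chromosome (``thom``, trans-homolog), or
pooled without haplotype assignment (``cis_pooled`` / ``reference_pooled``).
This module holds the bin grid (:class:`BinTable`), the sparse symmetric
matrix per channel (:class:`ContactMap`), iterative-correction balancing,
observed/expected normalization, and the empirical map-resolution pick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

CHANNELS = ("cis_maternal", "cis_paternal", "cis_pooled", "thom", "reference_pooled")


class FormatError(ValueError):
    """A record in an input file violates the declared format or bin grid."""


class BalancingError(RuntimeError):
    """Iterative correction failed to converge within the iteration cap."""


# ---------------------------------------------------------------------------
# Bin grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinTable:
    """A genome tiled into fixed-size bins, 0-based half-open coordinates.

    Bins tile each chromosome contiguously in coordinate order; every bin has
    a unique global integer index equal to its genomic rank.  The last bin of
    a chromosome may be shorter than ``bin_size``.
    """

    chromsizes: dict[str, int]
    bin_size: int
    bins: pd.DataFrame = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        rows = []
        for chrom, length in self.chromsizes.items():
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        object.__setattr__(self, "bins", pd.concat(rows, ignore_index=True))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slices(self) -> dict[str, slice]:
        """Global-index slice covering each chromosome, in genomic order."""
        out: dict[str, slice] = {}
        lo = 0
        for chrom, length in self.chromsizes.items():
            n = -(-length // self.bin_size)
            out[chrom] = slice(lo, lo + n)
            lo += n
        return out

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos`` on ``chrom``."""
        if chrom not in self.chromsizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chromsizes[chrom]):
            raise ValueError(f"position {pos} outside {chrom} (len {self.chromsizes[chrom]})")
        return self.chrom_slices()[chrom].start + pos // self.bin_size

    def to_chromsizes_file(self, path) -> None:
        pd.Series(self.chromsizes).to_csv(path, sep="\t", header=False)

    @classmethod
    def from_chromsizes_file(cls, path, bin_size: int) -> "BinTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df.chrom.astype(str), df.length.astype(int))), bin_size)


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

@dataclass
class ScoreTrack:
    """One value per genomic bin (NaN marks missing).

    ``kind`` names the statistic: pairing score (PS) and cis score (CS) are in
    log2 contact-frequency units, as is the insulation score; eigenvector,
    expression and ChIP enrichment are in their native units.  ``window`` is
    the half-width W in bins for windowed statistics.
    """

    bin_table: BinTable
    values: np.ndarray
    kind: str = "generic"
    window: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bin_table.n_bins,):
            raise ValueError("track length must equal number of bins")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Sparse symmetric binned contact matrix for one haplotype channel.

    Pixels are stored upper-triangular (i <= j) and interpreted symmetrically.
    ``weights`` holds per-bin iterative-correction factors (NaN at masked
    bins) once :func:`iterative_correction` has run; the balanced value of
    pixel (i, j) is ``count * weights[i] * weights[j]``.
    """

    bin_table: BinTable
    channel: str
    pixels: sp.csr_matrix
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_pixels(cls, bin_table: BinTable, channel: str,
                    i: np.ndarray, j: np.ndarray, counts: np.ndarray) -> "ContactMap":
        """Build from triplets, folding (i, j) and (j, i) into the upper triangle."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise FormatError("negative counts are not allowed")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        n = bin_table.n_bins
        mat = sp.coo_matrix((counts.astype(np.float64), (lo, hi)), shape=(n, n)).tocsr()
        mat.sum_duplicates()
        return cls(bin_table, channel, mat)

    # -- properties ----------------------------------------------------------

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the bin is excluded (missing weight)."""
        if self.weights is None:
            return np.zeros(self.bin_table.n_bins, dtype=bool)
        return ~np.isfinite(self.weights)

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric raw-count matrix (diagonal counted once)."""
        p = self.pixels
        return p + p.T - sp.diags(p.diagonal())

    def to_dense(self, chrom: str | None = None, balanced: bool = False) -> np.ndarray:
        """Dense symmetric matrix; balanced mode returns NaN at masked rows/cols."""
        sl = self.bin_table.chrom_slices()[chrom] if chrom else slice(None)
        sym = self.symmetric()[sl, sl]
        dense = np.asarray(sym.todense(), dtype=float)
        if balanced:
            if self.weights is None:
                raise ValueError("map is not balanced")
            w = self.weights[sl]
            dense = dense * np.outer(w, w)
        return dense

    def scaled(self, factor: float) -> "ContactMap":
        """Map with all raw counts multiplied by ``factor`` (weights dropped)."""
        return ContactMap(self.bin_table, self.channel, self.pixels * factor)


# ---------------------------------------------------------------------------
# I/O: TSV triplets (chrom1, start1, chrom2, start2, count)
# ---------------------------------------------------------------------------

def read_contact_map(path, channel: str, bin_table: BinTable) -> ContactMap:
    """Read a TSV triplet contact file onto a declared bin grid.

    Each row is ``chrom1 start1 chrom2 start2 count`` with starts on the bin
    grid.  Rows given in either orientation are folded into the upper
    triangle.  A sidecar ``<path>.weights`` file (chrom, start, end, weight),
    if present, restores balancing weights.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom1", "start1", "chrom2", "start2", "count"])
    except Exception as exc:  # noqa: BLE001 - report as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)].index[0]
        raise FormatError(f"malformed row {bad} in {path}")
    for col in ("start1", "start2"):
        off = df[col].to_numpy() % bin_table.bin_size != 0
        if off.any():
            row = df.iloc[int(np.flatnonzero(off)[0])]
            raise FormatError(f"coordinate off the {bin_table.bin_size}-bp grid: {tuple(row)}")
    if (df["count"] < 0).any():
        row = df.iloc[int((df["count"] < 0).idxmax())]
        raise FormatError(f"negative count in record {tuple(row)}")
    try:
        i = np.array([bin_table.bin_index(c, s) for c, s in zip(df.chrom1, df.start1)])
        j = np.array([bin_table.bin_index(c, s) for c, s in zip(df.chrom2, df.start2)])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"record outside the bin grid in {path}: {exc}") from exc
    cmap = ContactMap.from_pixels(bin_table, channel, i, j, df["count"].to_numpy())
    import os
    wpath = str(path) + ".weights"
    if os.path.exists(wpath):
        wdf = pd.read_csv(wpath, sep="\t", header=None,
                          names=["chrom", "start", "end", "weight"],
                          float_precision="round_trip")
        if len(wdf) != bin_table.n_bins:
            raise FormatError(f"weight sidecar {wpath} does not match the bin grid")
        cmap.weights = wdf["weight"].to_numpy(dtype=float)
    return cmap


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write upper-triangle pixels as a TSV triplet (plus a weight sidecar)."""
    coo = sp.triu(cmap.pixels).tocoo()
    bins = cmap.bin_table.bins
    df = pd.DataFrame({
        "chrom1": bins.chrom.to_numpy()[coo.row],
        "start1": bins.start.to_numpy()[coo.row],
        "chrom2": bins.chrom.to_numpy()[coo.col],
        "start2": bins.start.to_numpy()[coo.col],
        "count": coo.data,
    }).sort_values(["chrom1", "start1", "start2"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False)
    if cmap.weights is not None:
        wdf = bins.copy()
        wdf["weight"] = cmap.weights
        wdf.to_csv(str(path) + ".weights", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Iterative correction (matrix balancing)
# ---------------------------------------------------------------------------

def iterative_correction(cmap: ContactMap, mad_filter: float | None = 5.0,
                         tol: float = 1e-6, max_iter: int = 1000,
                         mask: np.ndarray | None = None) -> ContactMap:
    """Balance a contact map so every unmasked bin has the same marginal.

    The main diagonal is excluded from the marginals.  Bins with zero
    coverage, and bins whose log10 coverage falls more than ``mad_filter``
    median-absolute-deviations below the median (a one-sided low-coverage
    filter, as in the standard iterative-correction procedure), are masked;
    ``mad_filter=None`` disables the coverage filter, and ``mask`` forces
    additional bins out (e.g. to carry a visibility mask from a cis channel
    into the thom channel, whose low-coverage bins are biology, not
    artifact).  Weights are scaled so the balanced marginal of every
    unmasked bin equals the mean raw marginal — balancing removes per-bin
    visibility bias but preserves the overall count scale, which lets log2
    contact-frequency scores remain comparable across channels of different
    depth.
    """
    S = cmap.symmetric().astype(np.float64)
    S = S.tolil()
    S.setdiag(0.0)
    S = S.tocsr()
    cov = np.asarray(S.sum(axis=1)).ravel()
    masked = cov <= 0
    if mask is not None:
        masked |= np.asarray(mask, bool)
    nz = cov[~masked]
    if nz.size == 0:
        raise BalancingError("map has no off-diagonal signal")
    logc = np.log10(nz)
    med = np.median(logc)
    mad = np.median(np.abs(logc - med))
    if mad > 0 and mad_filter is not None:
        low = np.zeros_like(masked)
        low[~masked] = (logc - med) / mad < -mad_filter
        masked |= low
    if (~masked).sum() < 2:
        raise BalancingError("fewer than two bins survive the coverage filter")

    b = np.ones(cmap.bin_table.n_bins)
    b[masked] = 0.0
    spread = np.inf
    for _ in range(max_iter):
        marg = b * np.asarray(S @ b).ravel()
        m = marg[~masked]
        target = m.mean()
        if target <= 0:
            raise BalancingError("balanced marginals collapsed to zero")
        spread = np.abs(m / target - 1.0).max()
        if spread < tol:
            break
        adj = marg / target
        adj[masked] = 1.0
        adj[adj == 0] = 1.0
        b /= adj
    else:
        raise BalancingError(
            f"no convergence in {max_iter} iterations (marginal spread {spread:.3g})")

    # rescale so balanced marginals equal the mean raw marginal
    m0 = cov[~masked].mean()
    marg = b * np.asarray(S @ b).ravel()
    b *= np.sqrt(m0 / marg[~masked].mean())
    weights = b.copy()
    weights[masked] = np.nan
    return replace(cmap, weights=weights)


# ---------------------------------------------------------------------------
# Observed / expected
# ---------------------------------------------------------------------------

def observed_over_expected(cmap: ContactMap) -> dict[str, np.ndarray]:
    """Per-chromosome dense observed/expected matrices of balanced values.

    Expected at separation d is the mean balanced value over all valid pixels
    on that diagonal of the chromosome; masked pixels stay NaN.  Chromosomes
    with fewer than two unmasked bins are skipped with a warning.
    """
    if not cmap.is_balanced:
        raise ValueError("observed_over_expected requires a balanced map")
    out: dict[str, np.ndarray] = {}
    for chrom, sl in cmap.bin_table.chrom_slices().items():
        valid = ~cmap.mask[sl]
        if valid.sum() < 2:
            warnings.warn(f"skipping {chrom}: fewer than 2 unmasked bins")
            continue
        D = cmap.to_dense(chrom, balanced=True)
        n = D.shape[0]
        D[~valid, :] = np.nan
        D[:, ~valid] = np.nan
        oe = np.full_like(D, np.nan)
        for d in range(n):
            diag = np.diagonal(D, d)
            good = np.isfinite(diag)
            if not good.any():
                continue
            exp = diag[good].mean()
            if exp == 0:
                continue
            idx = np.arange(n - d)
            oe[idx, idx + d] = diag / exp
            oe[idx + d, idx] = diag / exp
        out[chrom] = oe
    return out


# ---------------------------------------------------------------------------
# Map resolution
# ---------------------------------------------------------------------------

@dataclass
class ResolutionReport:
    """Outcome of the empirical bin-size selection.

    For each candidate bin size the report holds the fraction of non-zero
    pixels per diagonal; the chosen size is the finest candidate whose
    fraction at the reference separation exceeds ``min_fraction``.
    """

    candidates: list[int]
    curves: dict[int, pd.DataFrame]
    reference_separation: int
    min_fraction: float
    chosen: int
    none_qualified: bool = False


def nonzero_diagonal_fraction(cmap: ContactMap, separation: int) -> float:
    """Fraction of non-zero pixels on the diagonal at ``separation`` bp."""
    bs = cmap.bin_table.bin_size
    if separation % bs != 0:
        raise ValueError(f"separation {separation} is not a multiple of bin size {bs}")
    d = separation // bs
    nonzero = total = 0
    for sl in cmap.bin_table.chrom_slices().values():
        n = sl.stop - sl.start
        if n <= d:
            continue
        sub = cmap.pixels[sl, sl]
        nonzero += int(np.count_nonzero(sub.diagonal(d)))
        total += n - d
    return nonzero / total if total else np.nan


def pick_resolution(maps: dict[int, ContactMap], reference_separation: int = 100_000,
                    min_fraction: float = 0.5, max_separation: int | None = None) -> ResolutionReport:
    """Pick the finest bin size keeping the reference diagonal mostly non-zero.

    Defaults encode the usual rule of thumb: the finest resolution with more
    than 50% non-zero pixels at 100 kb separation (roughly the domain scale).
    If no candidate qualifies, the coarsest is returned with a flag.
    """
    if not maps:
        raise ValueError("at least one candidate map is required")
    for bs in maps:
        if reference_separation % bs != 0:
            raise ValueError(f"reference separation must be a multiple of bin size {bs}")
    max_sep = max_separation or 2 * reference_separation
    curves: dict[int, pd.DataFrame] = {}
    fractions: dict[int, float] = {}
    for bs, cmap in maps.items():
        seps = np.arange(bs, max_sep + 1, bs)
        frac = np.array([nonzero_diagonal_fraction(cmap, int(s)) for s in seps])
        curves[bs] = pd.DataFrame({"separation": seps, "fraction": frac})
        fractions[bs] = nonzero_diagonal_fraction(cmap, reference_separation)
    qualifying = sorted(bs for bs, f in fractions.items() if f > min_fraction)
    if qualifying:
        chosen, flag = qualifying[0], False
    else:
        chosen, flag = max(maps), True
    return ResolutionReport(sorted(maps), curves, reference_separation,
                            min_fraction, chosen, flag)
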