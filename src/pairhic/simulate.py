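"""Synthetic diploid Hi-C maps with known ground truth.

The generator emulates the features of a haplotype-resolved contact map that
the downstream estimators consume: power-law distance decay, domains with
insulating boundaries, an A/B compartment plaid, and a trans-homolog (thom)
channel whose near-diagonal signal is enriched where homologs are tightly
paired and depleted inside loosely paired regions while preserved at region
boundaries.  Loosely paired regions are built as single large domains with no
internal boundaries; tightly paired regions are runs of small domains, so the
within-region contact-decay curve changes slope at the small-domain scale.

Counts are independent Poisson draws around a deterministic expected-value
model, so every expected map is exactly reproducible from the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinTable, ContactMap, ScoreTrack


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic diploid contact-map model.

    ``boundaries`` are interior domain edges as bin indices; domain k spans
    bins [edge_k, edge_{k+1}).  ``pairing_labels`` and ``compartment_labels``
    give one label per domain.  ``depth`` is the expected total cis count per
    cis channel; the thom channel's depth follows from the enrichment factors
    rather than being rescaled, so pairing strength shows up in thom coverage
    as it does in a real library.
    """

    chrom_length: int = 20_000_000
    bin_size: int = 4_000
    alpha: float = 1.0
    boundaries: tuple[int, ...] = ()
    insulation_depletion: float = 0.3
    compartment_labels: tuple[str, ...] = ()
    plaid_strength: float = 1.3
    pairing_labels: tuple[str, ...] = ()
    tight_enrichment: float = 0.7
    loose_depletion: float = 0.15
    loose_scale: int | None = None
    depth: float = 5e6
    seed: int = 0
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        n = self.n_bins
        b = np.asarray(self.boundaries, dtype=int)
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= n):
            raise ValueError("boundaries must be sorted, strictly interior bin indices")
        n_dom = b.size + 1
        for name, labels, allowed in (
            ("pairing_labels", self.pairing_labels, {"tight", "loose"}),
            ("compartment_labels", self.compartment_labels, {"A", "B"}),
        ):
            if labels and (len(labels) != n_dom or not set(labels) <= allowed):
                raise ValueError(f"{name} must give one of {allowed} per domain")
        if not (0 < self.insulation_depletion <= 1):
            raise ValueError("insulation_depletion must be in (0, 1]")
        if self.plaid_strength < 1:
            raise ValueError("plaid_strength must be >= 1")
        if self.tight_enrichment <= 0 or not (0 <= self.loose_depletion < 1):
            raise ValueError("invalid pairing multipliers")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    @property
    def bin_table(self) -> BinTable:
        return BinTable({self.chrom_name: self.chrom_length}, self.bin_size)

    def domain_edges(self) -> np.ndarray:
        return np.concatenate([[0], np.asarray(self.boundaries, int), [self.n_bins]])


@dataclass
class GroundTruth:
    """Per-bin labels and structural parameters the generator planted."""

    pairing_label: np.ndarray        # 'tight' / 'loose' per bin
    boundaries: np.ndarray           # interior domain-edge bin indices
    compartment_label: np.ndarray    # 'A' / 'B' per bin
    alpha: float
    low_depth: bool = False
    config: SimulationConfig | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Expected-value model
# ---------------------------------------------------------------------------

def _domain_ids(config: SimulationConfig) -> np.ndarray:
    edges = config.domain_edges()
    ids = np.zeros(config.n_bins, dtype=int)
    for k in range(len(edges) - 1):
        ids[edges[k]:edges[k + 1]] = k
    return ids


def _pairing_regions(config: SimulationConfig) -> list[tuple[int, int, str]]:
    """Runs of consecutive same-pairing-label domains as (lo_bin, hi_bin, label)."""
    edges = config.domain_edges()
    labels = config.pairing_labels or ("tight",) * (len(edges) - 1)
    regions = []
    k = 0
    while k < len(labels):
        k2 = k
        while k2 + 1 < len(labels) and labels[k2 + 1] == labels[k]:
            k2 += 1
        regions.append((int(edges[k]), int(edges[k2 + 1]), labels[k]))
        k = k2 + 1
    return regions


def loose_interior_mask(config: SimulationConfig) -> np.ndarray:
    """Bins strictly inside a loose region (region-edge bins stay tight)."""
    inside = np.zeros(config.n_bins, dtype=bool)
    for lo, hi, label in _pairing_regions(config):
        if label == "loose" and hi - lo > 2:
            inside[lo + 1:hi - 1] = True
    return inside


def expected_maps(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Dense expected-value matrices (lambda_cis, lambda_thom).

    lambda_cis(i,j) = C * max(s, bin)^(-alpha) * insulation factor (depleted
    across boundaries) * compartment plaid (boosted when labels match), with C
    set so the upper-triangle total equals the requested depth.  lambda_thom
    is lambda_cis times the tight enrichment, additionally depleted for pairs
    of bins inside the same loose region at separations below the loose
    length scale (default: the region's own span).
    """
    n = config.n_bins
    starts = np.arange(n, dtype=np.int64) * config.bin_size
    s = np.abs(starts[:, None] - starts[None, :])
    lam = np.maximum(s, config.bin_size).astype(np.float64) ** (-config.alpha)

    dom = _domain_ids(config)
    lam *= np.where(dom[:, None] == dom[None, :], 1.0, config.insulation_depletion)

    if config.compartment_labels:
        comp = np.array([config.compartment_labels[k] for k in dom])
        lam *= np.where(comp[:, None] == comp[None, :], config.plaid_strength, 1.0)

    total = np.triu(lam).sum()
    lam *= config.depth / total

    thom = lam * config.tight_enrichment
    interior = loose_interior_mask(config)
    for lo, hi, label in _pairing_regions(config):
        if label != "loose":
            continue
        scale = config.loose_scale if config.loose_scale is not None \
            else (hi - lo) * config.bin_size
        reg = np.zeros(n, dtype=bool)
        reg[lo:hi] = True
        sel = reg & interior
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        block = np.ix_(idx, idx)
        thom[block] = np.where(s[block] < scale,
                               thom[block] * config.loose_depletion, thom[block])
    return lam, thom


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_map(lam: np.ndarray, rng: np.random.Generator,
                bin_table: BinTable, channel: str) -> ContactMap:
    counts = np.triu(rng.poisson(lam))
    import scipy.sparse as sp
    mat = sp.csr_matrix(counts)
    return ContactMap(bin_table, channel, mat.astype(np.float64))


def simulate_diploid_maps(config: SimulationConfig
                          ) -> tuple[ContactMap, ContactMap, ContactMap, GroundTruth]:
    """Draw (cis_maternal, cis_paternal, thom) maps plus the ground truth.

    Both cis channels share one expected map (structurally concordant
    homologs) but are sampled independently; all counts are Poisson.  The
    same configuration and seed always give byte-identical pixel tables.
    """
    lam_cis, lam_thom = expected_maps(config)
    rng = np.random.default_rng(config.seed)
    bt = config.bin_table
    mat = _sample_map(lam_cis, rng, bt, "cis_maternal")
    pat = _sample_map(lam_cis, rng, bt, "cis_paternal")
    thom = _sample_map(lam_thom, rng, bt, "thom")

    first_diag = np.diagonal(lam_cis, 1)
    low_depth = bool(first_diag.size and first_diag.mean() < 1.0)

    interior = loose_interior_mask(config)
    pairing = np.where(interior, "loose", "tight")
    dom = _domain_ids(config)
    if config.compartment_labels:
        comp = np.array([config.compartment_labels[k] for k in dom])
    else:
        comp = np.full(config.n_bins, "A")
    truth = GroundTruth(pairing, np.asarray(config.boundaries, int), comp,
                        config.alpha, low_depth, config)
    return mat, pat, thom, truth


def simulate_ps_sample(weights, means, sds, n: int, seed: int = 0) -> np.ndarray:
    """Draw an i.i.d. sample from a two-component Gaussian mixture.

    Mirrors the generative model behind the pairing-score distribution: a
    high mode of tightly paired bins plus a low tail of loose ones.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    weights = np.asarray(weights, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(means[comp], sds[comp])


# ---------------------------------------------------------------------------
# Random genome structure and companion tracks
# ---------------------------------------------------------------------------

def random_structure(chrom_length: int = 20_000_000, bin_size: int = 4_000,
                     seed: int = 0, loose_probability: float = 0.3,
                     **overrides) -> SimulationConfig:
    """A realistic random domain/region layout for the default model.

    Loose regions are single domains of 100-400 kb; tight regions are runs of
    3-8 small domains of 32-52 kb each, so boundaries inside tight regions
    sit at the scale where within-region contact decay steepens.
    """
    rng = np.random.default_rng(seed)
    n = -(-chrom_length // bin_size)
    edges = [0]
    pairing: list[str] = []
    while edges[-1] < n:
        if rng.random() < loose_probability:
            size = int(rng.integers(25, 101))           # 100-400 kb at 4 kb bins
            edges.append(edges[-1] + size)
            pairing.append("loose")
        else:
            for _ in range(int(rng.integers(3, 9))):
                size = int(rng.integers(8, 14))         # 32-52 kb at 4 kb bins
                edges.append(edges[-1] + size)
                pairing.append("tight")
    # truncate to the chromosome
    edges = [e for e in edges if e < n] + [n]
    pairing = pairing[:len(edges) - 1]
    boundaries = tuple(edges[1:-1])
    comp = tuple(rng.choice(["A", "B"], size=len(pairing)))
    return SimulationConfig(chrom_length=chrom_length, bin_size=bin_size,
                            boundaries=boundaries,
                            pairing_labels=tuple(pairing),
                            compartment_labels=comp,
                            seed=seed, **overrides)


def gene_density_track(truth: GroundTruth, bin_table: BinTable,
                       seed: int = 0) -> ScoreTrack:
    """Synthetic per-bin gene-count track: A compartments are gene rich.

    Used to select and orient the compartment eigenvector, mirroring how the
    gene-density track anchors the A/B sign on real maps.
    """
    rng = np.random.default_rng(seed)
    lam = np.where(truth.compartment_label == "A", 5.0, 1.0)
    return ScoreTrack(bin_table, rng.poisson(lam).astype(float), kind="gene_count")
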