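"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from pairhic import BinTable, ContactMap


def dense_to_map(dense: np.ndarray, bin_size: int = 4000, chrom: str = "chr1",
                 channel: str = "cis_pooled", weights: np.ndarray | str | None = None
                 ) -> ContactMap:
    """ContactMap from a dense symmetric matrix; weights='ones' marks it balanced."""
    dense = np.asarray(dense, float)
    n = dense.shape[0]
    bt = BinTable({chrom: n * bin_size}, bin_size)
    cmap = ContactMap(bt, channel, sp.csr_matrix(np.triu(dense)))
    if isinstance(weights, str) and weights == "ones":
        cmap.weights = np.ones(n)
    elif weights is not None:
        cmap.weights = np.asarray(weights, float)
    return cmap


def random_sparse_map(n: int = 50, seed: int = 0, density: float = 0.3,
                      bin_size: int = 4000, channel: str = "cis_pooled") -> ContactMap:
    """Random upper-triangular integer-count map on an n-bin single chromosome."""
    rng = np.random.default_rng(seed)
    dense = rng.poisson(5.0, size=(n, n)) * (rng.random((n, n)) < density)
    dense = np.triu(dense)
    dense = dense + dense.T - np.diag(np.diag(dense))
    return dense_to_map(dense, bin_size=bin_size, channel=channel)


def toeplitz_map(n: int = 30, bin_size: int = 4000, decay: float = 1.0) -> ContactMap:
    """Translation-invariant balanced map: value depends only on |i-j|."""
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :]).astype(float)
    dense = (s + 1.0) ** (-decay) * 100
    return dense_to_map(dense, bin_size=bin_size, weights="ones")
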