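"""Compartment eigenvector, PS associations, loops, and disomy."""

import numpy as np
import pandas as pd
import pytest

import pairhic as ph

from helpers import dense_to_map


# ---------------------------------------------------------------------------
# Compartment eigenvector
# ---------------------------------------------------------------------------

def _two_block_map(n=40, c=0.5):
    """Balanced map whose O/E - 1 carries a two-block +-c checkerboard."""
    sigma = np.where(np.arange(n) < n // 2, 1.0, -1.0)
    s = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    base = 100.0 / (s + 1.0)
    dense = base * (1.0 + c * np.outer(sigma, sigma))
    return dense_to_map(dense, weights="ones"), sigma


def test_two_block_checkerboard_recovers_block_signs():
    cmap, sigma = _two_block_map()
    gene = ph.ScoreTrack(cmap.bin_table, np.where(sigma > 0, 5.0, 1.0),
                         kind="gene_count")
    ev, eigvals = ph.compartment_eigenvector(cmap, gene)
    assert np.all(np.sign(ev.values) == sigma)
    assert "chr1" in eigvals


def test_anticorrelated_eigenvector_is_returned_flipped():
    cmap, sigma = _two_block_map()
    gene = ph.ScoreTrack(cmap.bin_table, np.where(sigma > 0, 1.0, 5.0),
                         kind="gene_count")
    ev, _ = ph.compartment_eigenvector(cmap, gene)
    # orientation follows the gene track, so signs flip with it
    assert np.all(np.sign(ev.values) == -sigma)


def test_eigenvector_selection_invariant_to_gene_track_scaling():
    cmap, sigma = _two_block_map()
    g1 = ph.ScoreTrack(cmap.bin_table, np.where(sigma > 0, 5.0, 1.0))
    g2 = ph.ScoreTrack(cmap.bin_table, 100.0 * np.where(sigma > 0, 5.0, 1.0))
    ev1, _ = ph.compartment_eigenvector(cmap, g1)
    ev2, _ = ph.compartment_eigenvector(cmap, g2)
    np.testing.assert_allclose(ev1.values, ev2.values, atol=1e-10)


def test_synthetic_compartment_map_recovery():
    """|corr(EV, planted labels)| >= 0.95 on a compartment-dominated map."""
    rng = np.random.default_rng(0)
    edges = [0]
    while edges[-1] < 2000:
        edges.append(edges[-1] + int(rng.integers(40, 120)))
    edges = [e for e in edges if e < 2000] + [2000]
    cfg = ph.SimulationConfig(
        chrom_length=2000 * 4000, bin_size=4000,
        boundaries=tuple(edges[1:-1]), insulation_depletion=1.0,
        compartment_labels=tuple(rng.choice(["A", "B"], size=len(edges) - 1)),
        plaid_strength=2.0, depth=2e6, seed=11)
    mat, pat, _, truth = ph.simulate_diploid_maps(cfg)
    pooled = ph.ContactMap(cfg.bin_table, "cis_pooled", mat.pixels + pat.pixels)
    cis_b = ph.iterative_correction(pooled)
    gene = ph.gene_density_track(truth, cfg.bin_table, seed=1)
    ev, _ = ph.compartment_eigenvector(cis_b, gene)
    labels = (truth.compartment_label == "A").astype(float)
    good = np.isfinite(ev.values)
    corr = np.corrcoef(ev.values[good], labels[good])[0, 1]
    assert abs(corr) >= 0.95
    assert corr > 0          # oriented A-positive by the gene track


# ---------------------------------------------------------------------------
# Track correlation and quadrants
# ---------------------------------------------------------------------------

def _tracks(avals, bvals, bin_size=4000):
    bt = ph.BinTable({"chr1": len(avals) * bin_size}, bin_size)
    return (ph.ScoreTrack(bt, np.asarray(avals, float)),
            ph.ScoreTrack(bt, np.asarray(bvals, float)))


def test_spearman_extremes_and_rank_formula_oracle():
    rng = np.random.default_rng(41)
    x = rng.normal(size=20)
    a, b = _tracks(x, x)
    assert ph.track_correlation(a, b)[0] == pytest.approx(1.0)
    a, b = _tracks(x, -x)
    assert ph.track_correlation(a, b)[0] == pytest.approx(-1.0)
    y = rng.normal(size=20)
    a, b = _tracks(x, y)
    r, _ = ph.track_correlation(a, b)
    # rank-formula oracle: Pearson correlation of the rank vectors
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)


def test_constant_track_correlation_is_flagged_missing():
    a, b = _tracks(np.ones(20), np.arange(20))
    with pytest.warns(UserWarning, match="constant"):
        r, p = ph.track_correlation(a, b)
    assert np.isnan(r)


def test_quadrant_fractions_sum_to_one_and_match_hand_count():
    ps_vals = [1, 1, 1, -2, -2, 1, -2, 1, np.nan, 1]
    ev_vals = [3, 3, -1, 3, -1, -1, -1, 3, 3, np.nan]
    ps, ev = _tracks(ps_vals, ev_vals)
    q = ph.quadrant_fractions(ps, 0.0, ev, 0.0)
    # 8 joint bins: tight/high 3, tight/low 2, loose/high 1, loose/low 2
    assert q == {"tight_high": 3 / 8, "tight_low": 2 / 8,
                 "loose_high": 1 / 8, "loose_low": 2 / 8}
    assert sum(q.values()) == pytest.approx(1.0, abs=1e-15)
    all_tight, high = _tracks(np.ones(12), np.ones(12))
    q2 = ph.quadrant_fractions(all_tight, 0.0, high, 0.0)
    assert q2 == {"tight_high": 1.0, "tight_low": 0.0,
                  "loose_high": 0.0, "loose_low": 0.0}


# ---------------------------------------------------------------------------
# Mood's median test across chromatin states
# ---------------------------------------------------------------------------

def _state_frame(n_bins, states, bin_size=4000):
    rows = []
    for k, s in enumerate(states):
        rows.append(("chr1", k * (n_bins // len(states)) * bin_size,
                     (k + 1) * (n_bins // len(states)) * bin_size, s))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def test_moods_identical_samples_give_zero_chi_square():
    n = 80
    bt = ph.BinTable({"chr1": n * 4000}, 4000)
    vals = np.tile([0.1, 0.9, -0.4, 0.6], n // 4)
    ps = ph.ScoreTrack(bt, vals, kind="PS")
    states = _state_frame(n, ["yellow", "black"])
    out = ph.chromatin_state_association(ps, states, "yellow")
    row = out[out.state == "black"].iloc[0]
    assert row.chi_square == pytest.approx(0.0, abs=1e-12)
    assert row.p_value > 0.99


def test_moods_two_by_two_table_matches_hand_chi_square():
    """Counts [[30,10],[10,30]] above/below the pooled median give chi2 = 20."""
    n = 80
    bt = ph.BinTable({"chr1": n * 4000}, 4000)
    vals = np.concatenate([np.full(30, 2.0), np.full(10, 0.0),
                           np.full(10, 2.0), np.full(30, 0.0)])
    ps = ph.ScoreTrack(bt, vals, kind="PS")
    states = _state_frame(n, ["yellow", "black"])
    out = ph.chromatin_state_association(ps, states, "yellow")
    row = out[out.state == "black"].iloc[0]
    # hand formula: N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
    a, b, c, d = 30, 10, 10, 30
    expect = 80 * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert row.chi_square == pytest.approx(expect, abs=1e-12)


def test_moods_power_on_shifted_gaussians():
    rng = np.random.default_rng(43)
    n = 1000
    bt = ph.BinTable({"chr1": n * 4000}, 4000)
    vals = np.concatenate([rng.normal(0, 1, 500), rng.normal(1, 1, 500)])
    ps = ph.ScoreTrack(bt, vals, kind="PS")
    states = _state_frame(n, ["yellow", "black"])
    out = ph.chromatin_state_association(ps, states, "yellow")
    assert out[out.state == "black"].p_value.iloc[0] < 1e-6


def test_small_states_are_excluded_with_warning():
    n = 40
    bt = ph.BinTable({"chr1": n * 4000}, 4000)
    ps = ph.ScoreTrack(bt, np.random.default_rng(3).normal(size=n), kind="PS")
    states = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 120_000],
                           "end": [120_000, 140_000],
                           "state": ["yellow", "tiny"]})
    with pytest.warns(UserWarning, match="tiny"):
        out = ph.chromatin_state_association(ps, states, "yellow")
    assert "tiny" not in set(out.state)


# ---------------------------------------------------------------------------
# Loop quantitation
# ---------------------------------------------------------------------------

def test_loop_sums_zero_map_single_pixel_and_brute_force():
    n = 60
    bt_zero = dense_to_map(np.zeros((n, n)), weights="ones")
    loops = ph.LoopList(pd.DataFrame({"chrom": ["chr1"], "pos1": [80_000],
                                      "pos2": [160_000]}), window=120_000)
    out = ph.loop_quantitation(bt_zero, loops)
    assert out.balanced_sum.iloc[0] == 0.0

    dense = np.zeros((n, n))
    dense[22, 38] = dense[38, 22] = 7.0   # inside the window around (20, 40)
    cmap = dense_to_map(dense, weights="ones")
    out = ph.loop_quantitation(cmap, loops)
    assert out.balanced_sum.iloc[0] == pytest.approx(7.0)

    rng = np.random.default_rng(44)
    dense = rng.poisson(4, size=(n, n)).astype(float)
    dense = (dense + dense.T) / 2
    cmap = dense_to_map(dense, weights="ones")
    out = ph.loop_quantitation(cmap, loops)
    # brute force: 30x30 bins centered on the anchor pixel (20, 40)
    block = dense[20 - 15:20 + 15, 40 - 15:40 + 15]
    assert out.balanced_sum.iloc[0] == pytest.approx(block.sum(), rel=1e-12)
    assert not out.truncated.iloc[0]


def test_loop_window_truncated_at_chromosome_edge_is_flagged():
    n = 40
    cmap = dense_to_map(np.ones((n, n)), weights="ones")
    loops = ph.LoopList(pd.DataFrame({"chrom": ["chr1"], "pos1": [4_000],
                                      "pos2": [100_000]}), window=120_000)
    out = ph.loop_quantitation(cmap, loops)
    assert out.truncated.iloc[0]
    with pytest.raises(ValueError, match="off the assembly"):
        ph.loop_quantitation(cmap, ph.LoopList(pd.DataFrame(
            {"chrom": ["chr1"], "pos1": [4_000], "pos2": [999_000_000]})))


def test_masked_pixels_contribute_zero_to_loop_sums():
    n = 60
    dense = np.ones((n, n))
    w = np.ones(n)
    w[39] = np.nan
    cmap = dense_to_map(dense, weights=w)
    loops = ph.LoopList(pd.DataFrame({"chrom": ["chr1"], "pos1": [40_000],
                                      "pos2": [160_000]}), window=8_000)
    out = ph.loop_quantitation(cmap, loops)
    # 2x2 window with one masked column: only 2 pixels contribute
    assert out.balanced_sum.iloc[0] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# Disomy
# ---------------------------------------------------------------------------

def test_disomy_equal_coverage_gives_zero_fraction():
    est = ph.disomy_fraction(np.full(10, 3.0), np.full(10, 3.0))
    assert est.fraction == 0.0 and est.ratio == 1.0 and not est.swapped


def test_disomy_ratio_1_5_gives_fraction_0_2_exactly():
    est = ph.disomy_fraction(np.full(5, 1.5), np.full(5, 1.0))
    assert est.fraction == pytest.approx(0.2, abs=1e-15)
    # feeding the channels swapped recovers the same estimate, flagged
    est2 = ph.disomy_fraction(np.full(5, 1.0), np.full(5, 1.5))
    assert est2.fraction == pytest.approx(0.2, abs=1e-15) and est2.swapped


@pytest.mark.parametrize("x", np.linspace(0.0, 0.99, 12))
def test_disomy_round_trip_is_exact(x):
    r = ph.disomy_ratio_from_fraction(x)
    est = ph.disomy_fraction(np.array([r]), np.array([1.0]))
    assert est.fraction == pytest.approx(x, abs=1e-12)


def test_disomy_rejects_degenerate_input():
    with pytest.raises(ValueError):
        ph.disomy_fraction(np.array([]), np.array([1.0]))
    with pytest.raises(ValueError):
        ph.disomy_fraction(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
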