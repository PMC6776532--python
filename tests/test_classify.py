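"""Two-Gaussian deconvolution, thresholding, and region classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import pairhic as ph


TRUE = dict(weights=(0.7, 0.3), means=(0.0, -2.0), sds=(0.5, 0.6))


def _crossing_oracle(w1, m1, s1, w2, m2, s2, lo, hi, tol=1e-12):
    """Density-crossing point by bisection on a dense bracket (independent
    of the quadratic closed form used by the implementation)."""
    f = lambda x: w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)
    grid = np.linspace(lo, hi, 20_001)
    vals = f(grid)
    sign = np.sign(vals)
    idx = np.flatnonzero(np.diff(sign) != 0)[0]
    a, b = grid[idx], grid[idx + 1]
    while b - a > tol:
        mid = (a + b) / 2
        if np.sign(f(mid)) == np.sign(f(a)):
            a = mid
        else:
            b = mid
    return (a + b) / 2


def test_known_mixture_parameters_are_recovered():
    x = ph.simulate_ps_sample(TRUE["weights"], TRUE["means"], TRUE["sds"],
                              100_000, seed=21)
    fit = ph.fit_two_gaussians(x, clip_floor=-np.inf)
    assert fit.weight_tight == pytest.approx(0.7, abs=0.05)
    assert fit.weight_loose == pytest.approx(0.3, abs=0.05)
    assert fit.mean_tight == pytest.approx(0.0, abs=0.05)
    assert fit.mean_loose == pytest.approx(-2.0, abs=0.05)
    assert fit.sd_tight == pytest.approx(0.5, abs=0.05)
    assert fit.sd_loose == pytest.approx(0.6, abs=0.05)


def test_clip_floor_winsorizes_rather_than_discards():
    rng = np.random.default_rng(22)
    x = np.concatenate([rng.normal(0, 0.3, 5000), np.full(1000, -40.0)])
    fit = ph.fit_two_gaussians(x, clip_floor=-3.0)
    # the clipped tail survives as a component pinned at the floor
    assert fit.mean_loose == pytest.approx(-3.0, abs=0.1)
    assert fit.weight_loose == pytest.approx(1000 / 6000, abs=0.03)
    assert fit.clip_floor == -3.0


def test_default_clip_floor_is_minus_three():
    import inspect
    assert inspect.signature(ph.fit_two_gaussians).parameters["clip_floor"].default == -3.0


def test_single_gaussian_sample_is_flagged_unreliable():
    rng = np.random.default_rng(23)
    fit = ph.fit_two_gaussians(rng.normal(1.0, 0.5, 20_000), clip_floor=-np.inf)
    assert not fit.reliable
    # the two components sit inside one standard deviation of each other
    assert abs(fit.mean_tight - fit.mean_loose) < max(fit.sd_tight, fit.sd_loose)
    assert np.isfinite(fit.threshold)


def test_too_few_values_rejected():
    with pytest.raises(ValueError, match="500"):
        ph.fit_two_gaussians(np.zeros(100))


def test_threshold_is_midpoint_for_symmetric_components():
    fit = ph.GaussianMixtureFit(0.5, 0.5, -2.0, 0.0, 0.4, 0.4, -3.0,
                                np.nan, 0.0)
    assert ph.intersection_threshold(fit) == pytest.approx(-1.0, abs=1e-12)


def test_threshold_matches_independent_bisection_oracle():
    w1, w2 = 0.3, 0.7
    m1, m2 = -2.0, 0.0
    s1, s2 = 0.6, 0.5
    fit = ph.GaussianMixtureFit(w1, w2, m1, m2, s1, s2, -3.0, np.nan, 0.0)
    theta = ph.intersection_threshold(fit)
    oracle = _crossing_oracle(w1, m1, s1, w2, m2, s2, m1, m2)
    assert theta == pytest.approx(oracle, abs=1e-10)


def test_threshold_error_when_no_crossing_between_means():
    # extreme weight imbalance pushes the crossing outside (mu1, mu2)
    fit = ph.GaussianMixtureFit(1e-9, 1.0 - 1e-9, -0.5, 0.0, 0.5, 0.5, -3.0,
                                np.nan, 0.0)
    with pytest.raises(ValueError):
        ph.intersection_threshold(fit)


# ---------------------------------------------------------------------------
# Bin labels
# ---------------------------------------------------------------------------

def test_classify_bins_threshold_and_tie_rule():
    bt = ph.BinTable({"chr1": 5 * 4000}, 4000)
    ps = ph.ScoreTrack(bt, np.array([-1.0, -0.71, -0.5, np.nan, 0.2]), kind="PS")
    labels = ph.classify_bins(ps, -0.71)
    assert list(labels) == ["loose", "tight", "tight", "missing", "tight"]
    with pytest.raises(ValueError):
        ph.classify_bins(ps, np.nan)


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def _labels(spec_str):
    m = {"t": "tight", "l": "loose", ".": "missing"}
    return np.array([m[c] for c in spec_str], dtype=object)


def test_loose_fraction_rule_at_the_cutoff():
    bt = ph.BinTable({"chr1": 20 * 4000}, 4000)
    # two regions of 10 bins each: 0 loose -> tight; 3/10 loose -> loose
    labels = _labels("tttttttttt" + "lllttttttt")
    regions = ph.classify_regions(labels, [10], bt)
    df = regions.intervals
    assert list(df.label) == ["tight", "loose"]
    assert df.loose_fraction.iloc[1] == pytest.approx(0.3)
    # exactly at the cutoff counts as loose (>= 0.25)
    labels2 = _labels("tttttttttt" + "llttttttxt".replace("x", "t"))
    regions2 = ph.classify_regions(labels2, [10], bt, loose_cutoff=0.2)
    assert list(regions2.intervals.label) == ["tight", "loose"]


def test_merge_follows_boundary_bin_label_hand_oracle():
    """Five regions with hand-worked merge outcome.

    Regions (5 bins each): A=tight (0/5 loose), B=tight (0/5), C=loose
    (5/5), D=loose (2/5 >= 25%), E=tight (0/5).  Boundary bins: bin 5 is
    tight -> A+B merge; bin 10 is loose, labels differ -> no B+C merge;
    bin 15 is loose -> C+D merge; bin 20 is tight, labels differ -> no
    D+E merge.  Expected: [0,10)=tight, [10,20)=loose, [20,25)=tight.
    """
    bt = ph.BinTable({"chr1": 25 * 4000}, 4000)
    labels = _labels("ttttt" + "ttttt" + "lllll" + "llttt" + "ttttt")
    regions = ph.classify_regions(labels, [5, 10, 15, 20], bt)
    df = regions.intervals
    assert [(r.start, r.end, r.label) for r in df.itertuples()] == [
        (0, 10 * 4000, "tight"),
        (10 * 4000, 20 * 4000, "loose"),
        (20 * 4000, 25 * 4000, "tight"),
    ]


def test_missing_boundary_bin_blocks_merge_and_missing_region_never_merges():
    bt = ph.BinTable({"chr1": 15 * 4000}, 4000)
    labels = _labels("ttttt" + "." * 5 + "ttttt")
    regions = ph.classify_regions(labels, [5, 10], bt)
    df = regions.intervals
    assert list(df.label) == ["tight", "missing", "tight"]
    # a missing boundary-bin label blocks the merge across it, while the
    # matching 'tight' boundary bin at 10 still lets the last two regions fuse
    labels2 = _labels("ttttt" + ".tttt" + "ttttt")
    df2 = ph.classify_regions(labels2, [5, 10], bt).intervals
    assert [(r.start, r.end, r.label) for r in df2.itertuples()] == [
        (0, 5 * 4000, "tight"), (5 * 4000, 15 * 4000, "tight")]


def test_region_classification_is_idempotent(default_sim):
    regions = default_sim["regions"]
    bt = default_sim["bin_table"]
    edges = [bt.bin_index(r.chrom, r.start)
             for r in regions.intervals.itertuples()][1:]
    again = ph.classify_regions(default_sim["labels"], np.array(edges), bt)
    pd.testing.assert_frame_equal(regions.intervals, again.intervals)


def test_region_lengths_tile_the_genome(default_sim):
    regions = default_sim["regions"]
    assert regions.lengths().sum() == default_sim["config"].chrom_length
    df = regions.intervals
    assert (df.start.iloc[1:].to_numpy() == df.end.iloc[:-1].to_numpy()).all()


def test_select_regions_by_size_classes():
    df = pd.DataFrame({
        "chrom": ["chr1"] * 3, "start": [0, 500_000, 900_000],
        "end": [300_000, 650_000, 1_250_000],
        "label": ["tight", "loose", "tight"],
        "loose_fraction": [0.0, 0.5, 0.1],
    })
    regions = ph.PairingRegionSet(df)
    kept = ph.select_regions_by_size(regions, 200_000, 400_000)
    assert list(kept.intervals.end - kept.intervals.start) == [300_000, 350_000]
    kept2 = ph.select_regions_by_size(regions, 100_000, 200_000)
    assert list(kept2.intervals.end - kept2.intervals.start) == [150_000]
    assert len(ph.select_regions_by_size(regions, 1, 2).intervals) == 0
    with pytest.raises(ValueError):
        ph.select_regions_by_size(regions, 5, 5)
    from pairhic.classify import SIZE_CLASSES
    assert SIZE_CLASSES == {"100-200kb": (100_000, 200_000),
                            "200-400kb": (200_000, 400_000)}


def test_threshold_recovery_over_seeded_replicates():
    """|theta_hat - theta_analytic| <= 0.05 in >= 19/20 replicates at n=1e5."""
    analytic = _crossing_oracle(0.3, -2.0, 0.6, 0.7, 0.0, 0.5, -2.0, 0.0)
    hits = 0
    for seed in range(20):
        x = ph.simulate_ps_sample(TRUE["weights"], TRUE["means"], TRUE["sds"],
                                  100_000, seed=seed)
        fit = ph.fit_two_gaussians(x, clip_floor=-np.inf)
        hits += abs(fit.threshold - analytic) <= 0.05
    assert hits >= 19
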