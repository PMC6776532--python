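import numpy as np
import pytest

import pairhic as ph


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic diploid study: 20 Mb chromosome at 4 kb bins.

    Simulates the three channels, balances them (thom inherits the pooled
    cis visibility mask), and computes the score tracks, insulation
    boundaries, mixture fit and labels once for the whole session.
    """
    cfg = ph.random_structure(chrom_length=20_000_000, bin_size=4_000,
                              seed=1, depth=5e6)
    mat, pat, thom, truth = ph.simulate_diploid_maps(cfg)
    pooled = ph.ContactMap(cfg.bin_table, "cis_pooled", mat.pixels + pat.pixels)
    cis_b = ph.iterative_correction(pooled)
    thom_b = ph.iterative_correction(thom, mad_filter=None, mask=cis_b.mask)
    ps = ph.pairing_score(thom_b)
    cs = ph.pairing_score(cis_b)
    ins_cis = ph.insulation_score(cis_b)
    ins_thom = ph.insulation_score(thom_b)
    bnd_cis = ph.find_boundaries(ins_cis, 0.3, mask=cis_b.mask)
    bnd_thom = ph.find_boundaries(ins_thom, 0.3, mask=thom_b.mask)
    fit = ph.fit_two_gaussians(ps.values)
    labels = ph.classify_bins(ps, fit.threshold)
    regions = ph.classify_regions(labels, bnd_cis, cfg.bin_table)
    return {
        "config": cfg, "truth": truth, "bin_table": cfg.bin_table,
        "cis_raw": pooled, "thom_raw": thom,
        "cis": cis_b, "thom": thom_b,
        "ps": ps, "cs": cs,
        "insulation_cis": ins_cis, "insulation_thom": ins_thom,
        "boundaries_cis": bnd_cis, "boundaries_thom": bnd_thom,
        "fit": fit, "labels": labels, "regions": regions,
    }
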