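"""Insulation boundaries and contact-probability scaling curves.

Detects domain boundaries as prominent minima of the diamond insulation
track, checks them against the planted truth, and computes P(s) curves:
the thom/cis ratio, and within-region cis curves whose slope profile
separates domainized (tight) from unstructured (loose) chromatin.
"""

import numpy as np

import pairhic as ph

cfg = ph.random_structure(chrom_length=6_000_000, bin_size=4_000,
                          seed=2, depth=1.5e6)
mat, pat, thom, truth = ph.simulate_diploid_maps(cfg)
pooled = ph.ContactMap(cfg.bin_table, "cis_pooled", mat.pixels + pat.pixels)
cis = ph.iterative_correction(pooled)

track = ph.insulation_score(cis, w=5)
found = ph.find_boundaries(track, min_prominence=0.3, mask=cis.mask)
planted = ph.BoundarySet(truth.boundaries, np.zeros(len(truth.boundaries)), 0.0)
recall, precision = ph.boundary_overlap(planted, found, tolerance=4)
print(f"boundaries: {len(found)} called vs {len(planted)} planted "
      f"(recall {recall:.2f}, precision {precision:.2f} within 16 kb)")

p_cis = ph.contact_frequency_curve(mat, balanced=False)
p_thom = ph.contact_frequency_curve(thom, balanced=False)
ratio = ph.ratio_curve(p_thom, p_cis)
good = np.isfinite(ratio.P) & (ratio.n_pairs > 500)
print(f"median P_thom(s)/P_cis(s): {np.median(ratio.P[good]):.2f} "
      "(trans-homolog contacts track the cis decay at a constant fraction)")

tho = ph.iterative_correction(thom, mad_filter=None, mask=cis.mask)
ps = ph.pairing_score(tho)
fit = ph.fit_two_gaussians(ps.values)
labels = ph.classify_bins(ps, fit.threshold)
regions = ph.classify_regions(labels, found, cfg.bin_table)
curves = ph.region_restricted_curves(cis, regions)
for lab, cur in curves.items():
    slope = ph.log_slope(cur)
    band = (cur.s >= 10_000) & (cur.s <= 100_000) & np.isfinite(slope)
    print(f"{lab} regions: steepest cis slope {np.min(slope[band]):.2f} "
          f"in 10-100 kb")
print("Tight regions steepen at the small-domain scale (two decay modes); "
      "loose regions keep a single shallow power law.")
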