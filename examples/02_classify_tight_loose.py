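"""Classify the genome into tightly and loosely paired regions.

Fits the genome-wide pairing-score distribution with two Gaussians, places
the tight/loose threshold at their density crossing, labels bins, and then
groups bins into boundary-delimited regions (a region is loose once a
quarter of its bins are loose).
"""

import numpy as np

import pairhic as ph

cfg = ph.random_structure(chrom_length=4_000_000, bin_size=4_000,
                          seed=1, depth=1e6)
mat, pat, thom, truth = ph.simulate_diploid_maps(cfg)
pooled = ph.ContactMap(cfg.bin_table, "cis_pooled", mat.pixels + pat.pixels)
cis = ph.iterative_correction(pooled)
tho = ph.iterative_correction(thom, mad_filter=None, mask=cis.mask)
ps = ph.pairing_score(tho)

fit = ph.fit_two_gaussians(ps.values)
print(f"loose mode: N({fit.mean_loose:.2f}, {fit.sd_loose:.2f}), "
      f"weight {fit.weight_loose:.2f}")
print(f"tight mode: N({fit.mean_tight:.2f}, {fit.sd_tight:.2f}), "
      f"weight {fit.weight_tight:.2f}")
print(f"density-crossing threshold: PS = {fit.threshold:.3f}")

labels = ph.classify_bins(ps, fit.threshold)
scored = labels != "missing"
accuracy = (labels[scored] == truth.pairing_label[scored]).mean()
print(f"bin labels match the planted truth on {accuracy:.1%} of scored bins")

boundaries = ph.find_boundaries(ph.insulation_score(cis), 0.3, mask=cis.mask)
regions = ph.classify_regions(labels, boundaries, cfg.bin_table)
lengths = regions.lengths()
for lab in ("tight", "loose"):
    sel = (regions.intervals.label == lab).to_numpy()
    print(f"{lab}: {sel.sum()} regions covering "
          f"{lengths[sel].sum() / lengths.sum():.1%} of the chromosome")
print("Loose regions are the spans between insulating boundaries where the "
      "trans-homolog diagonal has dropped out.")
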