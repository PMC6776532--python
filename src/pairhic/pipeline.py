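"""End-to-end analysis pipeline: simulate/load, balance, score, classify.

``run_pipeline`` chains the whole analysis — synthetic map generation (or
loading TSV channel files), iterative correction, pairing and cis scores,
the two-Gaussian tight/loose classification, insulation boundaries, scaling
curves, compartment eigenvector, and the APS — and writes every stage output
plus a machine-readable JSON summary.  All randomness flows from one root
seed, so identical configurations give byte-identical summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import (MISSING, classify_bins, classify_regions, fit_two_gaussians)
from .core import (BinTable, ContactMap, iterative_correction, read_contact_map,
                   write_contact_map)
from .features import compartment_eigenvector, track_correlation
from .insulation import boundary_overlap, find_boundaries, insulation_score
from .io import (write_bedgraph, write_boundaries_bed, write_regions_bed,
                 write_scaling_tsv)
from .pairing import aggregated_pairing_score, pairing_difference, pairing_score
from .scaling import contact_frequency_curve, ratio_curve, region_restricted_curves
from .simulate import (GroundTruth, gene_density_track, random_structure,
                       simulate_diploid_maps)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; round-trips losslessly through YAML."""

    out_dir: str = "pairhic_out"
    seed: int = 0
    simulate: bool = True
    # synthetic-map parameters (used when simulate=True)
    chrom_length: int = 20_000_000
    bin_size: int = 4_000
    depth: float = 5e6
    alpha: float = 1.0
    tight_enrichment: float = 0.7
    loose_depletion: float = 0.15
    # input channel TSVs (used when simulate=False); chromsizes file required
    inputs: dict = field(default_factory=dict)
    chromsizes_file: str | None = None
    # analysis parameters
    window: int = 3
    insulation_width: int = 5
    min_prominence: float = 0.3
    clip_floor: float = -3.0
    loose_cutoff: float = 0.25
    mad_filter: float = 5.0
    balance_tol: float = 1e-6

    def validate(self) -> None:
        if self.window < 0 or self.insulation_width < 1:
            raise ValueError("window must be >= 0 and insulation width >= 1")
        if not (0 < self.loose_cutoff <= 1):
            raise ValueError("loose_cutoff must be in (0, 1]")
        if self.min_prominence <= 0 or self.balance_tol <= 0:
            raise ValueError("min_prominence and balance_tol must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    for key in ("out_dir", "inputs", "chromsizes_file"):  # paths, not science
        params.pop(key, None)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "parameters": _round_floats(params)}

    # ---- stage: obtain maps -------------------------------------------------
    truth: GroundTruth | None = None
    try:
        if config.simulate:
            sim = random_structure(config.chrom_length, config.bin_size,
                                   seed=config.seed, depth=config.depth,
                                   alpha=config.alpha,
                                   tight_enrichment=config.tight_enrichment,
                                   loose_depletion=config.loose_depletion)
            mat, pat, thom, truth = simulate_diploid_maps(sim)
            bt = sim.bin_table
            for cm, name in ((mat, "cis_maternal"), (pat, "cis_paternal"),
                             (thom, "thom")):
                write_contact_map(cm, out / f"{name}.tsv")
            _write_truth(truth, bt, out)
        else:
            if config.chromsizes_file is None:
                raise ValueError("chromsizes_file is required when simulate=False")
            bt = BinTable.from_chromsizes_file(config.chromsizes_file, config.bin_size)
            mat = read_contact_map(config.inputs["cis_maternal"], "cis_maternal", bt)
            pat = read_contact_map(config.inputs["cis_paternal"], "cis_paternal", bt)
            thom = read_contact_map(config.inputs["thom"], "thom", bt)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # ---- stage: balancing ---------------------------------------------------
    # The thom channel is balanced without its own coverage filter: loosely
    # paired regions legitimately have low thom coverage, so the visibility
    # mask is inherited from the pooled cis channel instead.
    try:
        pooled = ContactMap(bt, "cis_pooled", mat.pixels + pat.pixels)
        balanced = {}
        for cm in (mat, pat, pooled):
            balanced[cm.channel] = iterative_correction(
                cm, mad_filter=config.mad_filter, tol=config.balance_tol)
        balanced["thom"] = iterative_correction(
            thom, mad_filter=None, tol=config.balance_tol,
            mask=balanced["cis_pooled"].mask)
    except Exception as exc:
        raise RuntimeError(f"stage 'balance' failed: {exc}") from exc
    thom_b = balanced["thom"]
    cis_b = balanced["cis_pooled"]

    # ---- stage: scores ------------------------------------------------------
    ps = pairing_score(thom_b, W=config.window)
    cs = pairing_score(cis_b, W=config.window)
    write_bedgraph(ps, out / "ps.bedgraph")
    write_bedgraph(cs, out / "cs.bedgraph")
    aps = aggregated_pairing_score(ps, cs)
    summary["aps"] = aps

    # ---- stage: insulation and boundaries -----------------------------------
    ins_cis = insulation_score(cis_b, w=config.insulation_width)
    ins_thom = insulation_score(thom_b, w=config.insulation_width)
    write_bedgraph(ins_cis, out / "insulation_cis.bedgraph")
    bnd_cis = find_boundaries(ins_cis, config.min_prominence, channel="cis_pooled",
                              mask=cis_b.mask)
    bnd_thom = find_boundaries(ins_thom, config.min_prominence, channel="thom",
                               mask=thom_b.mask)
    write_boundaries_bed(bnd_cis, bt, out / "boundaries_cis.bed")
    write_boundaries_bed(bnd_thom, bt, out / "boundaries_thom.bed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ov_ct, ov_tc = boundary_overlap(bnd_cis, bnd_thom)
    summary["boundaries"] = {
        "n_cis": len(bnd_cis), "n_thom": len(bnd_thom),
        "cis_in_thom": ov_ct, "thom_in_cis": ov_tc,
    }

    # ---- stage: classification ----------------------------------------------
    fit = fit_two_gaussians(ps.values, clip_floor=config.clip_floor)
    labels = classify_bins(ps, fit.threshold)
    regions = classify_regions(labels, bnd_cis, bt, loose_cutoff=config.loose_cutoff)
    write_regions_bed(regions, out / "pairing_regions.bed")
    lengths = regions.lengths()
    total = lengths.sum()
    frac = {lab: float(lengths[(regions.intervals.label == lab).to_numpy()].sum() / total)
            for lab in ("tight", "loose", MISSING)}
    summary["mixture_fit"] = {
        "threshold": fit.threshold, "weight_loose": fit.weight_loose,
        "mean_loose": fit.mean_loose, "mean_tight": fit.mean_tight,
        "sd_loose": fit.sd_loose, "sd_tight": fit.sd_tight,
        "reliable": fit.reliable,
    }
    summary["genome_fractions"] = frac

    # ---- stage: scaling -----------------------------------------------------
    p_cis = contact_frequency_curve(cis_b)
    p_thom = contact_frequency_curve(thom_b)
    curves = [p_cis, p_thom, ratio_curve(p_thom, p_cis)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        restricted = region_restricted_curves(cis_b, regions)
    curves += list(restricted.values())
    write_scaling_tsv(curves, out / "scaling.tsv")
    ratio = ratio_curve(p_thom, p_cis)
    good = np.isfinite(ratio.P)
    summary["thom_cis_ratio_median"] = (float(np.median(ratio.P[good]))
                                        if good.any() else None)

    # ---- stage: compartments ------------------------------------------------
    if truth is not None:
        gene = gene_density_track(truth, bt, seed=config.seed + 1)
    else:
        gene = None
    if gene is not None:
        ev, _ = compartment_eigenvector(cis_b, gene)
        write_bedgraph(ev, out / "eigenvector.bedgraph")
        r_s, _ = track_correlation(ps, ev)
        summary["ps_eigenvector_spearman"] = r_s

    # ---- ground-truth comparison (synthetic runs) ---------------------------
    if truth is not None:
        from .insulation import BoundarySet
        planted = BoundarySet(truth.boundaries, np.zeros(len(truth.boundaries)), 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recall, precision = boundary_overlap(planted, bnd_cis)
        predicted = labels != MISSING
        acc = float((labels[predicted] == truth.pairing_label[predicted]).mean())
        summary["truth"] = {
            "bin_label_accuracy": acc,
            "boundary_recall": recall,
            "boundary_precision": precision,
            "n_bins_scored": int(predicted.sum()),
        }

    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    return summary


def _write_truth(truth: GroundTruth, bt: BinTable, out: Path) -> None:
    import pandas as pd
    bins = bt.bins
    df = pd.DataFrame({"chrom": bins.chrom, "start": bins.start, "end": bins.end,
                       "name": truth.pairing_label})
    df.to_csv(out / "truth_pairing.bed", sep="\t", header=False, index=False)
    cfg = asdict(truth.config) if truth.config is not None else {}
    (out / "truth_config.json").write_text(
        json.dumps(_round_floats(cfg), sort_keys=True, indent=2))
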