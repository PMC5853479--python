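"""End-to-end orchestration: simulate -> analyze -> report for all assays.

A single :class:`RunConfig` drives three stages — electrophysiology,
transcriptome and ratiometric imaging — on synthetic cohorts, writes each
stage's tables as tab-delimited text, and emits a combined JSON summary
plus a machine-readable manifest (seeds, thresholds, package version)
sufficient to reproduce every table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ephys import analyze_recording, compare_groups, nernst
from .imaging import compare_ratio_groups, compute_ratio, estimate_background, \
    segment_protoplasts
from .recording import ProtocolSpec
from .simulate import (
    BSC_CHANNEL_PARAMS,
    MC_CHANNEL_PARAMS,
    ChannelModelParams,
    ExpressionSimSpec,
    RatioImageSpec,
    simulate_expression_matrix,
    simulate_ratio_images,
    simulate_recording,
)
from .transcriptome import classify_transporters, differential_expression, \
    enrichment, expressed_genes, venn_summary

log = logging.getLogger("leafphys")

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds, seeds and cohort sizes for one pipeline run."""

    seed: int = 0
    temperature_k: float = 295.15
    ljp_table: dict = field(default_factory=lambda: {"low-K": -23.0, "30-K": -14.0})
    bath: str = "low-K"
    n_bsc: int = 8
    n_mc: int = 4
    expression_threshold: float = 2.0
    high_expression_threshold: float = 3.5
    fold_change_threshold: float = 1.5
    alpha: float = 0.05
    ramp_trim_ms: float = 2.0
    r2_gate: float = 0.99
    n_genes: int = 1000
    n_de_genes: int = 50
    de_log2_fc: float = 1.5
    n_protoplasts_per_group: int = 12
    bsc_potential_mv: float = -100.0
    mc_potential_mv: float = -60.0

    def validate(self):
        if self.bath not in self.ljp_table:
            raise ValueError(
                f"bath {self.bath!r} has no liquid-junction-potential entry"
            )
        for name in ("expression_threshold", "high_expression_threshold",
                     "fold_change_threshold", "alpha", "r2_gate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML document (missing keys use defaults)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**doc).validate()


def _ephys_stage(cfg: RunConfig, rng: np.random.Generator, outdir: Path) -> dict:
    ljp = cfg.ljp_table[cfg.bath]
    protocol = ProtocolSpec(ljp_mv=ljp)
    fits_by_type, rev_by_type, rows = {}, {}, []
    cohorts = (("BSC", BSC_CHANNEL_PARAMS, cfg.n_bsc),
               ("MC", MC_CHANNEL_PARAMS, cfg.n_mc))
    for cell_type, params, n in cohorts:
        fits, revs = [], []
        for i in range(n):
            seed = int(rng.integers(2**31 - 1))
            rec = simulate_recording(
                params, protocol, seed=seed, cell_type=cell_type,
                protoplast_id=f"{cell_type}_{i:02d}",
                temperature_k=cfg.temperature_k, bath=cfg.bath,
            )
            curve, fit, rev = analyze_recording(
                rec, trim_ms=cfg.ramp_trim_ms, r2_gate=cfg.r2_gate,
                temperature_k=cfg.temperature_k,
            )
            if not fit.converged:
                log.warning("non-convergent fit for %s: excluded", rec.protoplast_id)
                continue
            fits.append(fit)
            revs.append(rev.e_rev_mv)
            rows.append({
                "protoplast_id": rec.protoplast_id, "cell_type": cell_type,
                "g_basal": fit.g_basal, "g_max": fit.g_max,
                "g_max_net": fit.g_max_net, "e_half": fit.e_half, "z": fit.z,
                "e_rev": rev.e_rev_mv, "residual_norm": fit.residual_norm,
            })
        fits_by_type[cell_type] = fits
        rev_by_type[cell_type] = revs
    fit_table = pd.DataFrame(rows)
    fit_table.to_csv(outdir / "ephys_fits.tsv", sep="\t", index=False,
                     float_format="%.6g")
    comparison = compare_groups(fits_by_type)
    comparison.table.to_csv(outdir / "ephys_groups.tsv", sep="\t",
                            float_format="%.6g", index_label="parameter")
    holding_corrected = 0.0 + ljp
    p_o = {
        t: float(np.mean([float(f.open_fraction(holding_corrected)) for f in fits]))
        for t, fits in fits_by_type.items()
    }
    return {
        "e_half_difference_mv": comparison.mean_difference("e_half"),
        "e_half_p_value": comparison.p_value("e_half"),
        "mean_e_half": {t: float(np.mean([f.e_half for f in fs]))
                        for t, fs in fits_by_type.items()},
        "mean_e_rev_mv": {t: float(np.mean(v)) for t, v in rev_by_type.items()},
        "open_fraction_at_holding": p_o,
        "holding_potential_corrected_mv": holding_corrected,
    }


def _expression_stage(cfg: RunConfig, rng: np.random.Generator, outdir: Path) -> dict:
    seed = int(rng.integers(2**31 - 1))
    gene_rng = np.random.default_rng(seed)
    de_idx = gene_rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    signs = gene_rng.choice([-1.0, 1.0], size=cfg.n_de_genes)
    spec = ExpressionSimSpec(
        n_genes=cfg.n_genes,
        de_gene_indices=tuple(int(i) for i in de_idx),
        de_log2_fold_changes=tuple(cfg.de_log2_fc * s for s in signs),
        seed=seed,
    )
    matrix, truth = simulate_expression_matrix(spec)
    type_a, type_b = matrix.cell_types[:2]
    de = differential_expression(matrix, fc_threshold=cfg.fold_change_threshold,
                                 alpha=cfg.alpha)
    de.to_csv(outdir / "de_table.tsv", sep="\t", index_label="gene_id",
              float_format="%.6g")
    expr_a = expressed_genes(matrix, type_a, cfg.expression_threshold)
    expr_b = expressed_genes(matrix, type_b, cfg.expression_threshold)
    venn = venn_summary(expr_a, expr_b)
    pd.DataFrame([{
        f"{type_a}_only": venn.a_only, f"{type_b}_only": venn.b_only,
        "common": venn.common, "union": venn.union,
        "percent_common": venn.percent_common,
    }]).to_csv(outdir / "venn.tsv", sep="\t", index=False)
    classification = classify_transporters(
        matrix, matrix.annotations["transporter"], de,
        high_threshold=cfg.high_expression_threshold, alpha=cfg.alpha,
    )
    if len(classification.table):
        classification.table.to_csv(outdir / "transporter_groups.tsv", sep="\t")
    de_set = set(de.index[de["passed_de"]])
    enr = enrichment(
        de_set, matrix.annotations["category"], set(matrix.data.index),
        alpha=cfg.alpha, de_signs=de["signed_fold_change"],
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.6g")
    truth.to_csv(outdir / "expression_truth.tsv", sep="\t")
    return {
        "n_expressed": {type_a: len(expr_a), type_b: len(expr_b)},
        "venn_percent_common": venn.percent_common,
        "n_de": int(de["passed_de"].sum()),
        "n_de_p_only": int(de["passed_p_only"].sum()),
        "transporter_groups": {
            "A": len(classification.group_a), "B": len(classification.group_b),
            "C": len(classification.group_c),
        },
        "n_enriched_categories": int(enr["enriched"].sum()) if len(enr) else 0,
        "expression_seed": seed,
    }


def _imaging_stage(cfg: RunConfig, rng: np.random.Generator, outdir: Path) -> dict:
    seed = int(rng.integers(2**31 - 1))
    n = cfg.n_protoplasts_per_group
    # two interleaved rows of protoplasts on a grid, one group per row pair
    centers, groups, potentials = [], [], []
    img_rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(2 * n)))
    pitch = 60
    shape = (pitch * int(np.ceil(2 * n / cols)) + pitch, pitch * cols + pitch)
    k = 0
    for label, mean_pot in (("BSC", cfg.bsc_potential_mv), ("MC", cfg.mc_potential_mv)):
        for _ in range(n):
            r = pitch // 2 + pitch * (k // cols) + 10
            c = pitch // 2 + pitch * (k % cols) + 10
            centers.append((float(r), float(c)))
            groups.append(label)
            potentials.append(float(img_rng.normal(mean_pot, 5.0)))
            k += 1
    spec = RatioImageSpec(
        shape=shape, centers=tuple(centers), radii=tuple([18.0] * (2 * n)),
        potentials_mv=tuple(potentials), group_labels=tuple(groups), seed=seed,
    )
    pair = simulate_ratio_images(spec)
    rois = segment_protoplasts(pair.image_531)
    bg438 = estimate_background(pair.image_438, rois)
    bg531 = estimate_background(pair.image_531, rois)
    results = []
    truth = pair.truth
    for roi in rois:
        # match ROI to the nearest generated protoplast for its group label
        d = np.hypot(truth["center_row"] - roi.center[0],
                     truth["center_col"] - roi.center[1])
        grp = truth.loc[d.idxmin(), "group"]
        results.append(compute_ratio(roi, pair.image_438, pair.image_531,
                                     background_438=bg438, background_531=bg531,
                                     group=grp))
    pd.DataFrame([{
        "group": r.group, "mean_438": r.mean_438, "mean_531": r.mean_531,
        "ratio": r.ratio, "valid": r.valid,
    } for r in results]).to_csv(outdir / "ratios.tsv", sep="\t", index=False,
                                float_format="%.6g")
    table, summary = compare_ratio_groups(results)
    table.to_csv(outdir / "ratio_groups.tsv", sep="\t", index_label="group",
                 float_format="%.6g")
    return {
        "n_segmented": len(rois),
        "mean_ratio": {g: float(table.loc[g, "mean_ratio"]) for g in table.index},
        "ratio_p_value": summary["p_value"],
        "smaller_ratio_group": summary["smaller_ratio_group"],
        "imaging_seed": seed,
    }


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all three stages and write tables, summary and manifest.

    Returns the combined summary dict (also written as ``summary.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary = {"ephys": _ephys_stage(config, rng, outdir)}
    summary["expression"] = _expression_stage(config, rng, outdir)
    summary["imaging"] = _imaging_stage(config, rng, outdir)
    summary["nernst_e_k_mv"] = {
        "low-K": nernst(5.0, 140.0, 1, config.temperature_k),
        "30-K": nernst(30.0, 140.0, 1, config.temperature_k),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "package": "leafphys", "version": __version__,
        "config": asdict(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return summary
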