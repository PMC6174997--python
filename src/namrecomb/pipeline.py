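"""End-to-end pipeline: simulate a NAM population, phenotype crossovers,
map QTL in single families and jointly, classify cis/trans, test allele
additivity, merge QTL regions, and run the load/LD/IBD contrasts.

Configuration is a plain mapping (typically parsed from YAML); a single
global seed fans out to per-stage seeds that are recorded in the report.
The report directory contains one TSV per table, a ``MANIFEST.tsv``, and a
``report.json`` with the per-section summaries and a truth-vs-estimate
comparison.  Identical configurations (same seed) produce byte-identical
output.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import io
from .architecture import (
    CisTransCall,
    additivity_analysis,
    classify_cis_trans,
    favorable_allele_counts,
    merge_regions,
    overlap_summary,
)
from .genome import ArmPartition, GenomeModel, uniform_genome
from .genome_load import (
    annotation_to_bin_counts,
    define_high_recomb_regions,
    ibd_co_contrast,
    ld_per_bin,
    ld_recomb_correlation,
    load_contrast,
    make_bins,
)
from .phenotyping import call_crossovers, map_summary, summarize_phenotypes
from .qtl_joint import allele_effect_series, joint_stepwise
from .qtl_scan import QTLResult, scan_family
from .simulate import (
    ModifierSpec,
    add_genotyping_noise,
    simulate_annotation,
    simulate_founders,
    simulate_ssd_family,
)

logger = logging.getLogger(__name__)

SECTIONS = [
    "map", "phenotypes", "single_scans", "joint", "cis_trans",
    "additivity", "regions", "contrasts",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"n_chrom": 3, "length_cm": 200.0, "n_markers": 201},
    "founders": {"n": 4, "maf": 0.5, "ibd_fraction": 0.0},
    "families": {"n_families": 3, "n_rils": 100, "n_generations": 7},
    "modifiers": [],
    "noise": {"error_rate": 0.002, "missing_rate": 0.02},
    "scan": {"alpha": 0.05, "n_perm": 100, "window_cm": 10.0, "step_cm": 2.0},
    "traits": ["tco", "pco", "dco"],
    "annotation": {"theta": 2.0, "n_snps": 5000},
    "distal_fraction": 1.0 / 3.0,
}


def _merged_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def validate_config(config: dict) -> dict:
    """Fill defaults and check invariants; raises :class:`ConfigError`."""
    cfg = _merged_config(config)
    nf = int(cfg["families"]["n_families"])
    if nf < 1:
        raise ConfigError("n_families must be >= 1")
    alpha = float(cfg["scan"]["alpha"])
    bonf = alpha / nf
    cfg["scan"]["alphas"] = [alpha, bonf]
    for a in cfg["scan"]["alphas"]:
        if not 0 < a < 1:
            raise ConfigError(f"alpha {a} outside (0, 1)")
    n_perm = int(cfg["scan"]["n_perm"])
    if n_perm * min(cfg["scan"]["alphas"]) < 1:
        raise ConfigError(
            f"n_perm={n_perm} cannot resolve alpha={min(cfg['scan']['alphas']):g} "
            "(need n_perm * alpha >= 1)"
        )
    return cfg


def _build_model(cfg: dict) -> GenomeModel:
    g = cfg["genome"]
    if "chromosomes" in g:
        from .genome import build_genome_model

        return build_genome_model(g)
    return uniform_genome(
        n_chrom=int(g["n_chrom"]), length_cm=float(g["length_cm"]),
        n_markers=int(g["n_markers"]),
    )


def _parse_modifiers(cfg: dict, model: GenomeModel) -> list[ModifierSpec]:
    specs = []
    for m in cfg["modifiers"]:
        specs.append(
            ModifierSpec(
                chrom=m["chrom"],
                pos_cm=float(m["pos_cm"]),
                beta=float(m["beta"]),
                scope=m.get("scope", "global"),
                carriers=frozenset(m.get("carriers", ())),
            )
        )
    for s in specs:
        model.chrom(s.chrom)  # raises for off-map loci
    return specs


def run_pipeline(config: dict | None, out_dir: str) -> dict:
    """Run every stage and write the report bundle; returns the report."""
    cfg = validate_config(config or {})
    seed = int(cfg["seed"])
    rng_seeds = {name: (seed * 1009 + i * 104729) % (2**31 - 1)
                 for i, name in enumerate(
                     ["founders", "families", "noise", "scan", "annotation"], start=1)}
    t0 = time.time()
    report: dict = {"config": cfg, "seeds": rng_seeds, "sections": {}}
    tables: dict[str, pd.DataFrame] = {}

    model = _build_model(cfg)
    partition = ArmPartition.from_model(model, float(cfg["distal_fraction"]))
    modifiers = _parse_modifiers(cfg, model)
    gmap = model.marker_table()
    nf = int(cfg["families"]["n_families"])
    panel = simulate_founders(
        model,
        max(int(cfg["founders"]["n"]), nf + 1),
        maf_law=float(cfg["founders"]["maf"]),
        ibd_fraction=float(cfg["founders"]["ibd_fraction"]),
        seed=rng_seeds["founders"],
    )

    # --- simulate + phenotype ------------------------------------------------
    families = []
    pheno_frames = []
    cos_frames = []
    for f in range(1, nf + 1):
        genos, truth_cos, truth = simulate_ssd_family(
            panel, f, int(cfg["families"]["n_rils"]),
            int(cfg["families"]["n_generations"]), model,
            modifiers=modifiers, seed=rng_seeds["families"] + f,
            family=f"NAM{f}",
        )
        genos = add_genotyping_noise(
            genos, float(cfg["noise"]["error_rate"]),
            float(cfg["noise"]["missing_rate"]), seed=rng_seeds["noise"] + f,
        ).recode_het_missing()
        cos = call_crossovers(genos, gmap, k=2)
        pheno = summarize_phenotypes(cos, partition, genos=genos)
        families.append({"genos": genos, "cos": cos, "pheno": pheno, "truth": truth})
        pheno_frames.append(pheno.assign(family=genos.family).reset_index())
        cos_frames.append(cos.assign(family=genos.family))
    tables["phenotypes"] = pd.concat(pheno_frames, ignore_index=True)
    tables["crossovers"] = pd.concat(cos_frames, ignore_index=True)
    tables["map_summary"] = map_summary(gmap, model)
    report["sections"]["map"] = {
        "n_markers": int(model.n_markers),
        "total_length_cm": model.total_length_cm,
    }
    report["sections"]["phenotypes"] = {
        "mean_tco": float(tables["phenotypes"]["tco"].mean()),
        "mean_pco": float(tables["phenotypes"]["pco"].mean()),
        "mean_dco": float(tables["phenotypes"]["dco"].mean()),
        "n_rils": int(len(tables["phenotypes"])),
    }

    # --- single-family scans --------------------------------------------------
    scan_cfg = cfg["scan"]
    all_qtl: list[QTLResult] = []
    qtl_rows = []
    for i, fam in enumerate(families):
        for trait in cfg["traits"]:
            _prof, thr, qtl = scan_family(
                fam["pheno"], fam["genos"], gmap, trait=trait,
                alpha=scan_cfg["alphas"][0], n_perm=int(scan_cfg["n_perm"]),
                window_cm=float(scan_cfg["window_cm"]),
                step_cm=float(scan_cfg["step_cm"]),
                seed=rng_seeds["scan"] + i,
            )
            all_qtl.extend(qtl)
            for q in qtl:
                qtl_rows.append(vars(q) | {"family": fam["genos"].family})
    tables["qtl_single"] = pd.DataFrame(
        qtl_rows,
        columns=["trait", "family", "chrom", "peak_cm", "lod", "effect",
                 "ci_lo_cm", "ci_hi_cm", "threshold", "alpha"],
    )
    report["sections"]["single_scans"] = {
        "n_qtl": len(all_qtl),
        "alphas": scan_cfg["alphas"],
    }

    # --- joint mapping --------------------------------------------------------
    joint_inputs = [
        (fam["genos"], fam["pheno"]["tco"].to_numpy(dtype=float)) for fam in families
    ]
    jm = joint_stepwise(joint_inputs, gmap, p_enter=1e-4)
    tables["joint_effects"] = jm.effects
    tables["allele_series"] = allele_effect_series(jm)
    report["sections"]["joint"] = {
        "n_loci": len(jm.loci),
        "r2": jm.r2,
    }

    # --- cis/trans ------------------------------------------------------------
    ct_rows = []
    for fam in families:
        fam_qtl = [q for q in all_qtl if q.family == fam["genos"].family and q.trait == "tco"]
        for q in fam_qtl:
            call = classify_cis_trans(
                q, fam["cos"], fam["genos"], gmap, partition,
                n_perm=int(scan_cfg["n_perm"]), seed=rng_seeds["scan"] + 777,
                window_cm=float(scan_cfg["window_cm"]),
                step_cm=float(scan_cfg["step_cm"]),
            )
            ct_rows.append(
                {
                    "family": q.family, "trait": q.trait, "chrom": q.chrom,
                    "peak_cm": q.peak_cm, "classification": call.classification,
                }
            )
    tables["cis_trans"] = pd.DataFrame(
        ct_rows, columns=["family", "trait", "chrom", "peak_cm", "classification"]
    )
    n_trans = int((tables["cis_trans"]["classification"] == "trans").sum()) if len(ct_rows) else 0
    report["sections"]["cis_trans"] = {
        "n_classified": len(ct_rows),
        "n_trans": n_trans,
        "pct_trans": (round(100.0 * n_trans / len(ct_rows)) if ct_rows else None),
    }

    # --- additivity -----------------------------------------------------------
    add_rows = []
    for fam in families:
        fam_qtl = [q for q in all_qtl if q.family == fam["genos"].family and q.trait == "tco"]
        if len(fam_qtl) < 2:
            continue
        counts, usable = favorable_allele_counts(fam["genos"], gmap, fam_qtl)
        y = fam["pheno"]["tco"].to_numpy(dtype=float)
        try:
            res = additivity_analysis(y, counts, usable)
        except ValueError:
            continue
        add_rows.append(
            {
                "family": fam["genos"].family, "n_qtl": len(fam_qtl),
                "slope": res["slope"], "r2": res["r2"], "p": res["p"],
                "max_class_diff": res["max_class_diff"], "additive": res["additive"],
            }
        )
    tables["additivity"] = pd.DataFrame(
        add_rows,
        columns=["family", "n_qtl", "slope", "r2", "p", "max_class_diff", "additive"],
    )
    report["sections"]["additivity"] = {"n_families_tested": len(add_rows)}

    # --- regions --------------------------------------------------------------
    iv = tables["qtl_single"][tables["qtl_single"]["trait"] == "tco"]
    single_regions = merge_regions(
        iv.rename(columns={"ci_lo_cm": "start", "ci_hi_cm": "end"})[
            ["chrom", "start", "end", "family"]
        ]
    ) if len(iv) else merge_regions(pd.DataFrame(columns=["chrom", "start", "end"]))
    joint_iv = []
    for locus in jm.loci:
        chrom, cmtxt = locus.split("@")
        cmv = float(cmtxt[:-2])
        joint_iv.append({"chrom": chrom, "start": cmv - 5.0, "end": cmv + 5.0,
                         "family": "joint"})
    joint_regions = merge_regions(pd.DataFrame(joint_iv)) if joint_iv else merge_regions(
        pd.DataFrame(columns=["chrom", "start", "end"])
    )
    tables["regions_single"] = single_regions
    tables["regions_joint"] = joint_regions
    ov = overlap_summary(joint_regions, single_regions)
    report["sections"]["regions"] = {
        "n_single_regions": len(single_regions),
        "n_joint_regions": len(joint_regions),
        "overlap": ov,
    }

    # --- contrasts ------------------------------------------------------------
    bins = make_bins(model, tables["crossovers"], n_bins_per_chrom=10)
    bins, frac = define_high_recomb_regions(bins, distal_pct=10.0)
    ann = simulate_annotation(
        bins, float(cfg["annotation"]["theta"]), int(cfg["annotation"]["n_snps"]),
        seed=rng_seeds["annotation"],
    )
    counts = annotation_to_bin_counts(bins, ann)
    lc = load_contrast(counts)
    tables["bins"] = counts
    contrasts = {
        "captured_co_fraction": frac,
        "load_prop_high": lc["prop_high"],
        "load_prop_rest": lc["prop_rest"],
        "load_p": lc["p"],
    }
    mb = gmap.copy()
    widths = {c.name: c.length_cm / 10.0 for c in model.chromosomes}
    mb["bin"] = [
        min(int(cm // widths[ch]), 9) for ch, cm in zip(mb["chrom"], mb["cm"])
    ]
    ld = ld_per_bin(panel.alleles, mb[["chrom", "bin"]])
    merged_bins = counts.merge(ld, on=["chrom", "bin"], how="inner")
    try:
        r, p = ld_recomb_correlation(merged_bins)
        contrasts["ld_recomb_r"] = r
        contrasts["ld_recomb_p"] = p
    except ValueError as exc:
        contrasts["ld_recomb_r"] = None
        logger.info("LD correlation skipped: %s", exc)
    if float(cfg["founders"]["ibd_fraction"]) > 0:
        regions = []
        for c in model.chromosomes:
            w = c.length_cm / 10.0
            for s in np.arange(0.0, c.length_cm, w):
                regions.append({"chrom": c.name, "start_cm": s, "end_cm": s + w})
        fam_map = {
            fam["genos"].family: fam["genos"].alt_parent for fam in families
        }
        cos_all = tables["crossovers"]
        try:
            ibd = ibd_co_contrast(
                panel.ibd_tracts, cos_all, pd.DataFrame(regions), fam_map
            )
            contrasts["ibd_u"] = ibd["u"]
            contrasts["ibd_p"] = ibd["p"]
        except ValueError as exc:
            logger.info("IBD contrast skipped: %s", exc)
    report["sections"]["contrasts"] = contrasts

    # --- truth vs estimate ----------------------------------------------------
    truth_cmp = []
    for m in modifiers:
        best = None
        for q in all_qtl:
            if q.trait == "tco" and q.chrom == m.chrom:
                if best is None or abs(q.peak_cm - m.pos_cm) < abs(best.peak_cm - m.pos_cm):
                    best = q
        truth_cmp.append(
            {
                "chrom": m.chrom, "true_cm": m.pos_cm, "beta": m.beta,
                "scope": m.scope,
                "detected": best is not None,
                "est_cm": None if best is None else best.peak_cm,
                "est_effect": None if best is None else best.effect,
            }
        )
    report["truth_vs_estimate"] = truth_cmp
    logger.info("pipeline finished in %.1f s", time.time() - t0)

    os.makedirs(out_dir, exist_ok=True)
    io.write_results(tables, out_dir)
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
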