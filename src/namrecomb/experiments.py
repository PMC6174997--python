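"""Self-contained simulation studies exercising the whole pipeline.

Each function builds its own synthetic NAM data at a fixed desk-scale study
condition, runs the relevant pipeline stages, and returns a dict of summary
quantities.  These studies back both the validation test-suite and the
reproduction script; all randomness flows from the single ``seed`` argument.

Study conditions (chosen once; see the methods note for rationale):

* junction accumulation uses a 24-Morgan genome (8 chromosomes x 300 cM) —
  at the fully inbred limit selfed RILs accumulate 2 junctions per Morgan,
  so the expected total crossover count is ~48 per RIL, the scale typical
  of a hexaploid wheat genome;
* QTL studies use compact 6–12 Morgan genomes with ~1 marker/cM so that
  permutation scans stay fast while leaving realistic marker spacing;
* genotyping noise defaults to 0.2% allele-flip and 2% missing-call rates,
  the quality level of filtered array/sequencing genotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import codes
from .architecture import (
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
from .io import RILGenotypes
from .phenotyping import call_crossovers, summarize_phenotypes
from .qtl_joint import joint_stepwise
from .qtl_scan import scan_family
from .simulate import (
    ModifierSpec,
    add_genotyping_noise,
    calibrate_beta,
    divergent_panel,
    simulate_founders,
    simulate_ssd_family,
)

DEFAULT_ERROR_RATE = 0.002
DEFAULT_MISSING_RATE = 0.02


def _seed(seed: int, k: int) -> int:
    return (int(seed) * 1009 + k * 7919) % (2**31 - 1)


# ---------------------------------------------------------------------------
# junction accumulation


def junction_accumulation(seed: int = 1, n_rils: int = 2000) -> dict:
    """Mean true junction count of F7 SSD RILs on a 24-Morgan genome.

    The fully inbred selfed-RIL limit is 2 junctions per Morgan; at F7 the
    mean should sit within a few percent of 48 for a 24-Morgan map.
    """
    model = uniform_genome(n_chrom=8, length_cm=300.0, n_markers=4)
    panel = divergent_panel(model)
    _genos, _cos, truth = simulate_ssd_family(
        panel, "F01", n_rils, n_generations=7, model=model, seed=_seed(seed, 1)
    )
    mean_j = float(truth["junctions_true"].mean())
    return {
        "mean_junctions": mean_j,
        "mean_tco": float(truth["tco_true"].mean()),
        "per_morgan": mean_j / model.total_length_morgan,
        "limit": 2.0 * model.total_length_morgan,
        "n": n_rils,
    }


def residual_heterozygosity(seed: int = 1, n_rils: int = 2000) -> dict:
    """Observed per-locus heterozygote frequency in F7 lines (expect 1/64)."""
    model = uniform_genome(n_chrom=2, length_cm=100.0, n_markers=51)
    panel = divergent_panel(model)
    genos, _cos, _truth = simulate_ssd_family(
        panel, "F01", n_rils, n_generations=7, model=model, seed=_seed(seed, 2)
    )
    het = float((genos.calls == codes.HET).mean())
    return {"het_freq": het, "expected": 0.5**6, "n": n_rils * genos.n_markers}


# ---------------------------------------------------------------------------
# crossover caller


def _truth_marker_counts(
    truth_cos: pd.DataFrame, genos: RILGenotypes, gmap: pd.DataFrame, k: int
) -> pd.Series:
    """Independent oracle: per-RIL crossover counts expected from the true
    junction positions, projected onto the informative-marker grid and
    filtered with the k-consecutive-marker rule.

    Reconstructs the parental phase as a step function from the recorded
    junctions, evaluates it at each RIL's informative markers, and counts
    the surviving phase transitions — without touching the caller's code
    path through the genotype matrix.
    """
    gm = gmap.set_index("marker")
    chroms = gm.loc[genos.markers, "chrom"].to_numpy()
    cms = gm.loc[genos.markers, "cm"].to_numpy(dtype=float)
    counts = {r: 0 for r in genos.rils}
    jx_by = {
        key: sub.sort_values("pos_cm")
        for key, sub in truth_cos.groupby(["ril", "chrom"], sort=False)
    }
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        order = sel[np.argsort(cms[sel], kind="stable")]
        pos = cms[order]
        for j, ril in enumerate(genos.rils):
            col = genos.calls[order, j]
            inf = (col == codes.P1) | (col == codes.P2)
            mpos = pos[inf]
            if len(mpos) < max(k, 1):
                continue
            sub = jx_by.get((ril, chrom))
            if sub is None or len(sub) == 0:
                continue
            jpos = sub["pos_cm"].to_numpy(dtype=float)
            jto = sub["phase_to"].to_numpy()
            first_from = int(sub["phase_from"].iloc[0])
            # phase at marker = phase after the last junction before it
            idx = np.searchsorted(jpos, mpos, side="left")
            phases = np.where(idx == 0, first_from, jto[np.clip(idx - 1, 0, None)])
            # k-rule on the phase sequence
            change = np.flatnonzero(np.diff(phases) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(phases)]))
            keep = (ends - starts) >= k
            kph = phases[starts[keep]]
            merged = kph[np.concatenate(([True], np.diff(kph) != 0))] if len(kph) else kph
            counts[ril] += max(len(merged) - 1, 0)
    return pd.Series(counts)


def co_caller_study(seed: int = 1, n_rils: int = 150, error_rate: float = 0.005) -> dict:
    """Crossover-caller fidelity on a dense 2000-marker genome.

    Noise-free: called counts must match the truth-projection oracle
    exactly (both rules).  With per-marker error ``error_rate`` the mean
    per-RIL excess of the single-marker rule over the two-marker rule
    approaches ``2 * error_rate * M`` (each isolated miscall fakes two phase
    switches that the two-marker rule rejects).
    """
    model = uniform_genome(n_chrom=8, length_cm=300.0, n_markers=250)
    panel = divergent_panel(model)
    gmap = model.marker_table()
    genos, truth_cos, _truth = simulate_ssd_family(
        panel, "F01", n_rils, n_generations=7, model=model, seed=_seed(seed, 3)
    )
    clean = genos.recode_het_missing()
    res: dict = {"n": n_rils, "n_markers": model.n_markers}
    for k in (1, 2):
        called = call_crossovers(clean, gmap, k=k)
        cc = called.groupby("ril").size().reindex(clean.rils).fillna(0).astype(int)
        oracle = _truth_marker_counts(truth_cos, clean, gmap, k=k)
        res[f"clean_exact_k{k}"] = bool((cc == oracle.reindex(cc.index)).all())
        res[f"clean_mean_k{k}"] = float(cc.mean())
    noisy = add_genotyping_noise(clean, error_rate, 0.0, seed=_seed(seed, 4))
    noisy = noisy.recode_het_missing()
    c1 = call_crossovers(noisy, gmap, k=1).groupby("ril").size().reindex(noisy.rils).fillna(0)
    c2 = call_crossovers(noisy, gmap, k=2).groupby("ril").size().reindex(noisy.rils).fillna(0)
    m_inf = float(((noisy.calls == codes.P1) | (noisy.calls == codes.P2)).sum(axis=0).mean())
    res["k1_minus_k2_mean"] = float((c1 - c2).mean())
    res["expected_2eM"] = 2.0 * error_rate * m_inf
    res["k2_le_k1"] = bool((c2 <= c1).all())
    return res


# ---------------------------------------------------------------------------
# QTL recovery / cis-trans / additivity


def _qtl_genome(n_chrom: int = 3, length_cm: float = 200.0, n_markers: int = 201) -> GenomeModel:
    return uniform_genome(n_chrom=n_chrom, length_cm=length_cm, n_markers=n_markers)


def _calibrate_observed(
    panel, model, gmap, partition, target_effect: float, scope: str,
    chrom: str, pos_cm: float, seed: int, n_rils: int = 600, probe: float = 0.4,
) -> ModifierSpec:
    """Calibrate a modifier so that the *called*-phenotype class difference
    is close to ``target_effect`` crossovers.

    The observed effect is smaller than the true-mosaic effect because
    marker-resolution calling misses proportionally more double crossovers
    in high-intensity lines; two scaling rounds on the called phenotype
    absorb that attenuation.
    """
    # a single-chromosome modifier concentrates the whole effect on its own
    # chromosome: measure there (less noise) and start from a larger probe
    column = "tco" if scope != "chromosome" else f"co_{chrom}"
    beta = probe if scope != "chromosome" else 4 * probe
    for it in range(3):
        spec = ModifierSpec(chrom=chrom, pos_cm=pos_cm, beta=beta, scope=scope,
                            carriers=frozenset(("F01",)))
        _genos, _cos, pheno, truth = _family_phenotype(
            panel, model, gmap, partition, [spec], n_rils, seed + it
        )
        y = pheno[column].to_numpy(dtype=float)
        d = truth["dosage_0"].to_numpy(dtype=float)
        eff = float(y[d == 1.0].mean() - y[d == 0.0].mean())
        scale = np.clip(target_effect / eff if eff > 0 else 4.0, 0.25, 4.0)
        beta = float(beta * scale)
    return ModifierSpec(chrom=chrom, pos_cm=pos_cm, beta=beta, scope=scope,
                        carriers=frozenset(("F01",)))


def _family_phenotype(
    panel, model, gmap, partition, modifiers, n_rils, seed,
    error_rate=DEFAULT_ERROR_RATE, missing_rate=DEFAULT_MISSING_RATE,
):
    genos, truth_cos, truth = simulate_ssd_family(
        panel, "F01", n_rils, n_generations=7, model=model,
        modifiers=modifiers, seed=seed,
    )
    genos = add_genotyping_noise(genos, error_rate, missing_rate, seed=seed + 1)
    genos = genos.recode_het_missing()
    cos = call_crossovers(genos, gmap, k=2)
    pheno = summarize_phenotypes(cos, partition, genos=genos)
    return genos, cos, pheno, truth


def qtl_recovery(seed: int = 1, n_reps: int = 20, n_rils: int = 150, n_perm: int = 200) -> dict:
    """Power and accuracy for a single global recombination modifier.

    One global modifier is calibrated to a realized effect of ~ +4
    crossovers (RIL-level class difference) on a 6-Morgan genome with one
    marker per cM.  Detection requires a significant peak (family-wise 5%
    permutation threshold) within 10 cM of the true locus.
    """
    model = _qtl_genome()
    gmap = model.marker_table()
    partition = ArmPartition.from_model(model)
    panel = divergent_panel(model)
    true_chrom, true_cm = "chr1", 100.0
    spec = _calibrate_observed(
        panel, model, gmap, partition, 4.0, "global", true_chrom, true_cm,
        seed=_seed(seed, 6),
    )
    detected = 0
    biases: list[float] = []
    for rep in range(n_reps):
        s = _seed(seed, 10 + rep)
        genos, _cos, pheno, truth = _family_phenotype(
            panel, model, gmap, partition, [spec], n_rils, s
        )
        _prof, _thr, qtl = scan_family(
            pheno, genos, gmap, trait="tco", alpha=0.05, n_perm=n_perm, seed=s + 2
        )
        hits = [q for q in qtl if q.chrom == true_chrom and abs(q.peak_cm - true_cm) <= 10.0]
        if hits:
            detected += 1
            est = max(hits, key=lambda q: q.lod)
            y = pheno["tco"].to_numpy(dtype=float)
            d = truth["dosage_0"].to_numpy(dtype=float)
            realized = float(y[d == 1.0].mean() - y[d == 0.0].mean())
            biases.append(abs(est.effect) - realized)
    return {
        "power": detected / n_reps,
        "effect_bias": float(np.mean(biases)) if biases else float("nan"),
        "beta": spec.beta,
        "n_reps": n_reps,
        "n": n_rils,
    }


def cis_trans_study(seed: int = 1, n_reps: int = 20, n_rils: int = 200, n_perm: int = 200) -> dict:
    """Sensitivity / specificity of the leave-chromosome-out classifier.

    Trans truth: a global modifier (affects every chromosome).  Cis truth: a
    local modifier inflating only its own chromosome's crossovers.  Both
    are calibrated to ~ +4 total crossovers so the original QTL is found
    reliably; classification is evaluated among replicates where it is.
    """
    model = _qtl_genome()
    gmap = model.marker_table()
    partition = ArmPartition.from_model(model)
    panel = divergent_panel(model)
    locus = ("chr1", 100.0)
    spec_trans = _calibrate_observed(
        panel, model, gmap, partition, 4.0, "global", locus[0], locus[1],
        seed=_seed(seed, 21),
    )
    spec_cis = _calibrate_observed(
        panel, model, gmap, partition, 4.0, "chromosome", locus[0], locus[1],
        seed=_seed(seed, 22),
    )
    out = {}
    for label, spec in (("trans", spec_trans), ("cis", spec_cis)):
        correct = 0
        classified = 0
        for rep in range(n_reps):
            s = _seed(seed, 100 + rep + (0 if label == "trans" else 500))
            genos, cos, pheno, _truth = _family_phenotype(
                panel, model, gmap, partition, [spec], n_rils, s
            )
            _prof, _thr, qtl = scan_family(
                pheno, genos, gmap, trait="tco", alpha=0.05, n_perm=n_perm, seed=s + 2
            )
            hits = [
                q for q in qtl
                if q.chrom == locus[0] and abs(q.peak_cm - locus[1]) <= 15.0
            ]
            if not hits:
                continue
            classified += 1
            call = classify_cis_trans(
                max(hits, key=lambda q: q.lod), cos, genos, gmap, partition,
                n_perm=n_perm, seed=s + 3,
            )
            if call.classification == label:
                correct += 1
        out[f"{label}_correct"] = correct
        out[f"{label}_classified"] = classified
        out[f"{label}_rate"] = correct / classified if classified else float("nan")
    out["n_reps"] = n_reps
    out["n"] = n_rils
    return out


def additivity_study(seed: int = 1, n_rils: int = 600) -> dict:
    """Allele stacking with four equal-effect global modifiers (~ +3 each).

    Regression of the crossover count on the number of high alleles carried
    should recover the single-modifier per-allele effect (measured
    independently at the same beta by Monte Carlo); the modifiers act
    multiplicatively on intensity with a linear dosage term, so their
    stacked effect stays close to additive.
    """
    from .simulate import realized_modifier_effect

    model = uniform_genome(n_chrom=4, length_cm=300.0, n_markers=301)
    gmap = model.marker_table()
    partition = ArmPartition.from_model(model)
    panel = divergent_panel(model)
    probe = calibrate_beta(
        panel, "F01", model, 3.0, scope="global", chrom="chr1", pos_cm=150.0,
        carriers=("F01",), n_rils=1200, seed=_seed(seed, 31),
    )
    reference = realized_modifier_effect(
        panel, "F01", model, probe, n_rils=2000, seed=_seed(seed, 33)
    )
    specs = [
        ModifierSpec(chrom=c, pos_cm=150.0, beta=probe.beta, scope="global",
                     carriers=frozenset(("F01",)))
        for c in model.chrom_names
    ]
    genos, _cos, pheno, truth = _family_phenotype(
        panel, model, gmap, partition, specs, n_rils, _seed(seed, 32)
    )
    # allele counts from the true modifier dosages (fixed classes only)
    dos = truth[[f"dosage_{i}" for i in range(len(specs))]].to_numpy()
    fixed = np.all((dos == 0.0) | (dos == 1.0), axis=1)
    counts = dos.sum(axis=1).astype(int)
    y = truth["tco_true"].to_numpy(dtype=float)
    res = additivity_analysis(y, counts, usable=fixed)
    return {
        "slope": res["slope"],
        "per_allele_effect": float(reference),
        "slope_ratio": res["slope"] / float(reference),
        "r2": res["r2"],
        "p": res["p"],
        "max_class_diff": res["max_class_diff"],
        "n": int(fixed.sum()),
    }


def pericentromeric_study(seed: int = 1, n_rils: int = 200) -> dict:
    """Stacked pericentromeric-targeted modifiers move pCO, not dCO.

    Two modifiers scoped to the pericentromeric arm regions are stacked;
    the regression of pCO on the high-allele count should be significantly
    positive while the dCO regression stays flat.
    """
    model = uniform_genome(n_chrom=4, length_cm=300.0, n_markers=301)
    gmap = model.marker_table()
    partition = ArmPartition.from_model(model)
    panel = divergent_panel(model)
    probe = calibrate_beta(
        panel, "F01", model, 3.0, scope="pericentromeric", chrom="chr1",
        pos_cm=150.0, carriers=("F01",), n_rils=600, seed=_seed(seed, 41),
    )
    specs = [
        ModifierSpec(chrom=c, pos_cm=150.0, beta=probe.beta,
                     scope="pericentromeric", carriers=frozenset(("F01",)))
        for c in ("chr1", "chr2")
    ]
    genos, cos, pheno, truth = _family_phenotype(
        panel, model, gmap, partition, specs, n_rils, _seed(seed, 42)
    )
    dos = truth[["dosage_0", "dosage_1"]].to_numpy()
    fixed = np.all((dos == 0.0) | (dos == 1.0), axis=1)
    counts = dos.sum(axis=1).astype(int)
    pheno = pheno.loc[truth["ril"]]
    res_p = additivity_analysis(pheno["pco"].to_numpy(dtype=float), counts, usable=fixed)
    res_d = additivity_analysis(pheno["dco"].to_numpy(dtype=float), counts, usable=fixed)
    return {
        "pco_slope": res_p["slope"],
        "pco_p": res_p["p"],
        "dco_slope": res_d["slope"],
        "dco_p": res_d["p"],
        "n": int(fixed.sum()),
    }


# ---------------------------------------------------------------------------
# null calibration


def null_scan_calibration(seed: int = 1, n_reps: int = 200, n_rils: int = 100,
                          n_perm: int = 200) -> dict:
    """Genome-wide false-positive rate of the permutation-thresholded
    interval scan with no modifiers segregating (expect ~ alpha).

    Cofactor selection is disabled here: keeping data-selected cofactors
    fixed across permutations (the fast default) deflates the null max-LOD
    and inflates the realized rate to ~9-10%; the plain interval scan shows
    the calibration of the permutation threshold itself.
    """
    model = _qtl_genome()
    gmap = model.marker_table()
    partition = ArmPartition.from_model(model)
    panel = divergent_panel(model)
    fp = 0
    for rep in range(n_reps):
        s = _seed(seed, 1000 + rep)
        genos, _cos, pheno, _truth = _family_phenotype(
            panel, model, gmap, partition, [], n_rils, s
        )
        _prof, _thr, qtl = scan_family(
            pheno, genos, gmap, trait="tco", alpha=0.05, n_perm=n_perm, seed=s + 2,
            select=False,
        )
        if qtl:
            fp += 1
    return {"fpr": fp / n_reps, "alpha": 0.05, "n_reps": n_reps, "n": n_rils}


def null_joint_calibration(seed: int = 1, n_reps: int = 20, n_families: int = 5,
                           n_rils: int = 80) -> dict:
    """Share of null replicates where joint stepwise selects no marker at
    the strict entry threshold (expect >= 95% at p_enter 1e-4)."""
    model = _qtl_genome()
    gmap = model.marker_table()
    partition = ArmPartition.from_model(model)
    panel = simulate_founders(model, n_families + 1, maf_law=0.5, seed=_seed(seed, 60))
    empty = 0
    for rep in range(n_reps):
        fams = []
        for f in range(1, n_families + 1):
            s = _seed(seed, 2000 + rep * 31 + f)
            genos, truth_cos, _truth = simulate_ssd_family(
                panel, f, n_rils, n_generations=7, model=model, seed=s
            )
            genos = add_genotyping_noise(
                genos, DEFAULT_ERROR_RATE, DEFAULT_MISSING_RATE, seed=s + 1
            ).recode_het_missing()
            cos = call_crossovers(genos, gmap, k=2)
            pheno = summarize_phenotypes(cos, partition, genos=genos)
            fams.append((genos, pheno["tco"].to_numpy(dtype=float)))
        jm = joint_stepwise(fams, gmap, p_enter=1e-4)
        if not jm.loci:
            empty += 1
    return {"share_empty": empty / n_reps, "n_reps": n_reps,
            "n": n_families * n_rils}


# ---------------------------------------------------------------------------
# load / LD / IBD


def load_contrast_power(seed: int = 1, n_reps: int = 20, n_snps: int = 10_000,
                        theta: float = 2.0) -> dict:
    """Detection rate of deleterious-load enrichment at odds theta.

    Bins and their high-recombination flags come from one simulated family
    on a 24-Morgan genome; annotations are redrawn per replicate."""
    from .simulate import simulate_annotation

    model = uniform_genome(n_chrom=8, length_cm=300.0, n_markers=4)
    panel = divergent_panel(model)
    _genos, truth_cos, _truth = simulate_ssd_family(
        panel, "F01", 300, n_generations=7, model=model, seed=_seed(seed, 70)
    )
    bins = make_bins(model, truth_cos, n_bins_per_chrom=20)
    bins, _frac = define_high_recomb_regions(bins, distal_pct=10.0)
    rej = 0
    last_p = float("nan")
    for rep in range(n_reps):
        ann = simulate_annotation(bins, theta, n_snps, seed=_seed(seed, 80 + rep))
        counts = annotation_to_bin_counts(bins, ann)
        res = load_contrast(counts)
        last_p = res["p"]
        if res["p"] < 0.05:
            rej += 1
    return {"power": rej / n_reps, "theta": theta, "n_reps": n_reps,
            "n": n_snps, "last_p": last_p}


def ld_recomb_study(seed: int = 1, n_founders: int = 29) -> dict:
    """Founder LD vs meiotic recombination across bins.

    Founders are drawn with a copying chain whose decay tracks a
    distally-peaked intensity profile; meiotic crossovers are simulated
    with the same profile, so bin-level mean r² should correlate negatively
    with the bin's breakpoint count.
    """
    model = uniform_genome(n_chrom=3, length_cm=200.0, n_markers=201)

    def intensity(chrom: str, pos: np.ndarray) -> np.ndarray:
        scaled = np.asarray(pos) / 200.0
        return 0.25 + 3.0 * ((scaled < 0.15) | (scaled > 0.85))

    panel = simulate_founders(
        model, n_founders, maf_law=0.5, seed=_seed(seed, 90),
        ld_corr_cm=8.0, ld_intensity=intensity,
    )
    regions = {
        c.name: [(0.0, 30.0, 3.25), (30.0, 170.0, 0.25), (170.0, 200.0, 3.25)]
        for c in model.chromosomes
    }
    rng = np.random.default_rng(_seed(seed, 91))
    rows = []
    from .simulate import gamete

    hapA = (np.array([0.0]), np.array([0], dtype=np.int8))
    hapB = (np.array([0.0]), np.array([1], dtype=np.int8))
    for _ in range(400):
        for c in model.chromosomes:
            _g, xo = gamete(rng, hapA, hapB, c.length_cm, regions=regions[c.name])
            for p in xo:
                rows.append({"ril": "x", "chrom": c.name, "pos_cm": p})
    cos = pd.DataFrame(rows, columns=["ril", "chrom", "pos_cm"])
    bins = make_bins(model, cos, n_bins_per_chrom=10)
    gmap = model.marker_table()
    mb = gmap.copy()
    mb["bin"] = [
        min(int(cm // 20.0), 9) for cm in mb["cm"]
    ]
    ld = ld_per_bin(panel.alleles, mb[["chrom", "bin"]])
    merged = bins.merge(ld, on=["chrom", "bin"], how="inner")
    r, p = ld_recomb_correlation(merged)
    return {"pearson_r": r, "p": p, "n_bins": len(merged), "n": n_founders}


def ibd_co_study(seed: int = 1, n_rils: int = 200, boost: float = 2.0) -> dict:
    """IBD regions given elevated crossover intensity are detected by the
    Mann-Whitney contrast of per-region crossover counts."""
    model = uniform_genome(n_chrom=8, length_cm=300.0, n_markers=4)
    panel = simulate_founders(
        model, 2, maf_law=0.5, ibd_fraction=0.30, seed=_seed(seed, 95),
        mean_tract_cm=40.0,
    )
    _genos, truth_cos, _truth = simulate_ssd_family(
        panel, "F01", n_rils, n_generations=7, model=model,
        seed=_seed(seed, 96), ibd_intensity=boost,
    )
    regions = []
    for c in model.chromosomes:
        for s in np.arange(0.0, c.length_cm, 20.0):
            regions.append({"chrom": c.name, "start_cm": s, "end_cm": s + 20.0})
    res = ibd_co_contrast(
        panel.ibd_tracts, truth_cos.assign(family="fam"), pd.DataFrame(regions),
        family_founders={"fam": "F01"},
    )
    res["n"] = len(regions)
    return res


# ---------------------------------------------------------------------------
# worked arithmetic on region bookkeeping


def region_bookkeeping_examples() -> dict:
    """Overlap accounting on deterministic region sets: 13 of 20 joint
    regions intersecting a 27-region single-family set gives 65% / 48%."""
    single = pd.DataFrame(
        [{"chrom": f"c{i}", "start": 0.0, "end": 10.0, "family": f"f{i}"} for i in range(27)]
    )
    joint_rows = []
    for i in range(20):
        if i < 13:  # overlaps single region i
            joint_rows.append({"chrom": f"c{i}", "start": 5.0, "end": 15.0, "family": "joint"})
        else:
            joint_rows.append({"chrom": f"c{i}", "start": 50.0, "end": 60.0, "family": "joint"})
    joint = pd.DataFrame(joint_rows)
    a = merge_regions(joint)
    b = merge_regions(single)
    ov = overlap_summary(a, b)
    return {
        "pct_joint_in_single": ov["pct_a_in_b"],
        "pct_single_in_joint": ov["pct_b_in_a"],
        "n_a": ov["n_a"],
        "n_b": ov["n_b"],
    }
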