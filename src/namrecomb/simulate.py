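"""Forward simulation of a nested association mapping (NAM) population.

The simulator produces families of recombinant inbred lines (RILs) derived
by single-seed-descent selfing from crosses between a shared common parent
and a panel of diverse founders.  Every downstream stage of the pipeline
(crossover calling, QTL mapping, cis/trans classification, load contrasts)
can therefore be exercised against known ground truth.

Model choices
-------------
* Crossovers per meiosis follow a homogeneous Poisson process on genetic
  distance (Haldane model: no interference, no obligate crossover), so a
  chromosome of length L cM receives on average L/100 crossovers per meiosis
  and the cM unit keeps its textbook meaning.
* Recombination-rate modifiers act multiplicatively on the meiotic crossover
  intensity: a plant with dosage ``d`` of the high allele at a modifier of
  effect ``beta`` recombines at ``(1 + beta * d)`` times the base intensity
  within the modifier's scope (whole genome, one chromosome, or the
  pericentromeric regions only).  Heterozygous plants have dosage 0.5, so the
  modifier's influence changes as it segregates during inbreeding; the
  RIL-level crossover-count effect is emergent, not asserted, and can be
  measured with :func:`realized_modifier_effect`.
* Founders are fully inbred.  Identity-by-descent (IBD) tracts shared with
  the common parent are injected by copying the common parent's alleles.

Haplotypes are piecewise-constant founder-origin mosaics stored as
``(breakpoints, origins)`` arrays; origin 0 is the common parent, 1 the
alternate founder of the cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import codes
from .genome import ArmPartition, GenomeModel
from .io import RILGenotypes

Hap = tuple[np.ndarray, np.ndarray]  # (breakpoints starting at 0.0, origins)


# ---------------------------------------------------------------------------
# founders


@dataclass
class FounderPanel:
    """Homozygous founder haplotypes plus IBD tracts with the common parent.

    ``alleles`` has shape ``(n_founders, n_markers)`` with 0/1 entries in
    model marker order (chromosomes concatenated).  Row 0 is the common
    parent.
    """

    founders: list[str]
    alleles: np.ndarray
    ibd_tracts: pd.DataFrame  # columns: founder, chrom, start_cm, end_cm
    common_parent: str = ""

    def __post_init__(self) -> None:
        if not self.common_parent:
            self.common_parent = self.founders[0]
        self.alleles = np.asarray(self.alleles, dtype=np.int8)

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def founder_index(self, name: str) -> int:
        return self.founders.index(name)


def _marker_offsets(model: GenomeModel) -> dict[str, tuple[int, int]]:
    off = {}
    start = 0
    for c in model.chromosomes:
        n = len(model.markers[c.name])
        off[c.name] = (start, start + n)
        start += n
    return off


def simulate_founders(
    model: GenomeModel,
    n_founders: int,
    maf_law: "float | Callable[[np.random.Generator, int], np.ndarray]" = 0.5,
    ibd_fraction: float = 0.0,
    seed: int | None = None,
    mean_tract_cm: float = 30.0,
    ld_corr_cm: float = 0.0,
    ld_intensity: Callable[[str, np.ndarray], np.ndarray] | None = None,
) -> FounderPanel:
    """Draw a panel of inbred founder haplotypes.

    ``maf_law`` is either a fixed minor-allele frequency or a callable
    drawing per-marker frequencies.  ``ibd_fraction`` is the genome fraction
    of each non-common founder forced identical-by-descent to the common
    parent (tract lengths exponential with mean ``mean_tract_cm``).

    ``ld_corr_cm`` > 0 switches the per-founder allele draw to a Markov
    copying chain along each chromosome: adjacent markers share an allele
    with probability ``exp(-d * i / ld_corr_cm)`` where ``d`` is their cM
    separation and ``i`` an optional local intensity from ``ld_intensity``.
    This produces linkage disequilibrium among founders that decays with the
    (scaled) local recombination intensity — higher intensity, faster decay.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders (common parent + 1)")
    if not 0 <= ibd_fraction < 1:
        raise ValueError("ibd_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_markers = model.n_markers
    if callable(maf_law):
        freqs = np.asarray(maf_law(rng, n_markers), dtype=float)
    else:
        freqs = np.full(n_markers, float(maf_law))

    alleles = np.empty((n_founders, n_markers), dtype=np.int8)
    off = _marker_offsets(model)
    if ld_corr_cm > 0:
        for c in model.chromosomes:
            lo, hi = off[c.name]
            pos = model.markers[c.name]
            d = np.diff(pos)
            inten = np.ones(d.size) if ld_intensity is None else np.asarray(
                ld_intensity(c.name, (pos[:-1] + pos[1:]) / 2), dtype=float
            )
            p_copy = np.exp(-d * inten / ld_corr_cm)
            for f in range(n_founders):
                col = np.empty(hi - lo, dtype=np.int8)
                col[0] = rng.random() < freqs[lo]
                fresh = rng.random(d.size) >= p_copy
                draws = (rng.random(d.size) < freqs[lo + 1 : hi]).astype(np.int8)
                for j in range(d.size):
                    col[j + 1] = draws[j] if fresh[j] else col[j]
                alleles[f, lo:hi] = col
    else:
        alleles[:] = rng.random((n_founders, n_markers)) < freqs[None, :]

    founders = ["CP"] + [f"F{i:02d}" for i in range(1, n_founders)]
    tract_rows = []
    if ibd_fraction > 0:
        total = model.total_length_cm
        lengths = np.array([c.length_cm for c in model.chromosomes])
        probs = lengths / lengths.sum()
        for f in range(1, n_founders):
            covered: dict[str, list[tuple[float, float]]] = {c.name: [] for c in model.chromosomes}
            target = ibd_fraction * total

            def _covered_total() -> float:
                return sum(
                    e - s for iv in covered.values() for s, e in _merge_intervals(iv)
                )

            while _covered_total() < target - 0.25:
                ci = rng.choice(len(model.chromosomes), p=probs)
                c = model.chromosomes[ci]
                tlen = min(rng.exponential(mean_tract_cm), c.length_cm)
                tlen = min(tlen, target - _covered_total() + 1e-9)
                start = rng.uniform(0, c.length_cm - tlen) if c.length_cm > tlen else 0.0
                covered[c.name].append((start, start + tlen))
            for cname, tracts in covered.items():
                merged = _merge_intervals(tracts)
                lo, hi = off[cname]
                pos = model.markers[cname]
                for s, e in merged:
                    tract_rows.append(
                        {"founder": founders[f], "chrom": cname, "start_cm": s, "end_cm": e}
                    )
                    sel = (pos >= s) & (pos < e)
                    alleles[f, lo:hi][sel] = alleles[0, lo:hi][sel]
    ibd = pd.DataFrame(tract_rows, columns=["founder", "chrom", "start_cm", "end_cm"])
    return FounderPanel(founders=founders, alleles=alleles, ibd_tracts=ibd)


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# meiosis


@dataclass(frozen=True)
class ModifierSpec:
    """A recombination-rate modifier locus.

    ``beta`` is the multiplicative intensity increment per high allele; with
    dosage ``d`` in {0, 0.5, 1} the meiotic intensity within the scope is
    multiplied by ``1 + beta * d`` (summed over modifiers before applying).
    ``scope`` is ``"global"`` (whole genome), ``"chromosome"`` (the locus's
    own chromosome only; a cis-style local effect), or ``"pericentromeric"``
    (inner arm regions of every chromosome).  ``carriers`` names the founders
    whose allele at the locus is the high allele.
    """

    chrom: str
    pos_cm: float
    beta: float
    scope: str = "global"
    carriers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.scope not in ("global", "chromosome", "pericentromeric"):
            raise ValueError(f"unknown modifier scope {self.scope!r}")
        object.__setattr__(self, "carriers", frozenset(self.carriers))


def _validate_modifiers(model: GenomeModel, modifiers: Sequence[ModifierSpec]) -> None:
    for m in modifiers:
        c = model.chrom(m.chrom)  # KeyError -> off-map
        if not 0 <= m.pos_cm <= c.length_cm:
            raise ValueError(f"modifier locus {m.chrom}:{m.pos_cm} off the map")
    # intensity must stay positive at full dosage of every modifier
    worst = 1.0 + sum(min(m.beta, 0.0) for m in modifiers)
    if worst <= 0:
        raise ValueError("modifier betas drive intensity non-positive at full dosage")


def gamete(
    rng: np.random.Generator,
    hap_a: Hap,
    hap_b: Hap,
    length_cm: float,
    regions: Sequence[tuple[float, float, float]] | None = None,
    multiplier: float = 1.0,
) -> tuple[Hap, list[float]]:
    """Simulate one meiotic product of a diploid ``(hap_a, hap_b)``.

    ``regions`` is an optional partition ``[(start, end, multiplier), ...]``
    of the chromosome; missing coverage defaults to ``multiplier``.  Returns
    the gamete haplotype and the crossover positions (cM).  The crossover
    count is Poisson with mean ``sum(mult * span) / 100``.
    """
    if regions is None:
        regions = [(0.0, length_cm, multiplier)]
    xo: list[float] = []
    for s, e, m in regions:
        if m <= 0:
            raise ValueError("intensity multiplier must be positive")
        lam = m * (e - s) / 100.0
        k = rng.poisson(lam)
        if k:
            xo.extend(rng.uniform(s, e, k))
    xo.sort()
    first = int(rng.integers(2))
    haps = (hap_a, hap_b)
    if not xo:
        bp, org = haps[first]
        return (bp.copy(), org.copy()), xo
    bounds = [0.0] + xo + [length_cm]
    out_bp: list[float] = []
    out_org: list[int] = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        bp, org = haps[(first + i) % 2]
        j = int(np.searchsorted(bp, s, side="right")) - 1
        out_bp.append(s)
        out_org.append(int(org[j]))
        j += 1
        while j < len(bp) and bp[j] < e:
            out_bp.append(float(bp[j]))
            out_org.append(int(org[j]))
            j += 1
    cb = [out_bp[0]]
    co = [out_org[0]]
    for p, o in zip(out_bp[1:], out_org[1:]):
        if o != co[-1]:
            cb.append(p)
            co.append(o)
    return (np.asarray(cb), np.asarray(co, dtype=np.int8)), xo


def simulate_meiosis(
    genotype: dict[str, tuple[Hap, Hap]],
    model: GenomeModel,
    intensity: "float | dict[str, list[tuple[float, float, float]]]" = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Hap], dict[str, list[float]]]:
    """One whole-genome meiosis: a gamete haplotype per chromosome plus the
    true crossover positions.

    ``intensity`` is a global multiplier or a per-chromosome region list
    ``{chrom: [(start, end, mult), ...]}``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gam: dict[str, Hap] = {}
    xovers: dict[str, list[float]] = {}
    for c in model.chromosomes:
        h_a, h_b = genotype[c.name]
        if isinstance(intensity, dict):
            regions = intensity.get(c.name)
            g, xo = gamete(rng, h_a, h_b, c.length_cm, regions=regions)
        else:
            g, xo = gamete(rng, h_a, h_b, c.length_cm, multiplier=float(intensity))
        gam[c.name] = g
        xovers[c.name] = xo
    return gam, xovers


def _origin_at(hap: Hap, pos: float) -> int:
    bp, org = hap
    return int(org[int(np.searchsorted(bp, pos, side="right")) - 1])


def _modifier_dosage(genotype: dict[str, tuple[Hap, Hap]], m: ModifierSpec,
                     carrier_by_origin: tuple[bool, bool]) -> float:
    h0, h1 = genotype[m.chrom]
    d = 0.0
    for h in (h0, h1):
        if carrier_by_origin[_origin_at(h, m.pos_cm)]:
            d += 0.5
    return d


def _modifier_regions(
    model: GenomeModel,
    modifiers: Sequence[ModifierSpec],
    dosages: Sequence[float],
    partition: ArmPartition,
) -> "float | dict[str, list[tuple[float, float, float]]]":
    """Fold modifier dosages into per-chromosome intensity regions."""
    g_mult = 1.0
    chrom_extra: dict[str, float] = {}
    peri_extra = 0.0
    for m, d in zip(modifiers, dosages):
        contrib = m.beta * d
        if m.scope == "global":
            g_mult += contrib
        elif m.scope == "chromosome":
            chrom_extra[m.chrom] = chrom_extra.get(m.chrom, 0.0) + contrib
        else:  # pericentromeric
            peri_extra += contrib
    if not chrom_extra and peri_extra == 0.0:
        return g_mult
    regions: dict[str, list[tuple[float, float, float]]] = {}
    for c in model.chromosomes:
        base = g_mult + chrom_extra.get(c.name, 0.0)
        if peri_extra:
            lo, _cen, hi = partition.boundaries[c.name]
            regions[c.name] = [
                (0.0, lo, base),
                (lo, hi, base + peri_extra),
                (hi, c.length_cm, base),
            ]
        else:
            regions[c.name] = [(0.0, c.length_cm, base)]
    return regions


# ---------------------------------------------------------------------------
# single-seed-descent families


def _diploid_junctions(h0: Hap, h1: Hap) -> list[tuple[float, int, int]]:
    """Observable phase junctions of a diploid mosaic.

    Merges both haplotypes into dosage segments (0 = common-parent
    homozygote, 1 = het, 2 = alternate homozygote), drops the heterozygous
    segments, and returns ``(position, phase_from, phase_to)`` for every
    transition between the remaining homozygous phases.  A junction hidden
    inside a dropped het gap is placed at the gap midpoint.
    """
    bp = np.union1d(h0[0], h1[0])
    # dosage on each elementary segment
    o0 = h0[1][np.searchsorted(h0[0], bp, side="right") - 1]
    o1 = h1[1][np.searchsorted(h1[0], bp, side="right") - 1]
    dos = o0.astype(np.int16) + o1
    segs: list[tuple[float, int]] = []  # (start, dosage), compressed
    for p, d in zip(bp, dos):
        if not segs or segs[-1][1] != d:
            segs.append((float(p), int(d)))
    out: list[tuple[float, int, int]] = []
    prev_phase: int | None = None
    prev_end_start: float | None = None  # start of the segment after the last hom one
    last_hom_end: float | None = None
    for i, (start, d) in enumerate(segs):
        if d == 1:
            continue
        phase = 0 if d == 0 else 1
        if prev_phase is not None and phase != prev_phase:
            # position: boundary if adjacent, midpoint of the het gap otherwise
            pos = start if last_hom_end is None or last_hom_end == start else (last_hom_end + start) / 2.0
            out.append((pos, prev_phase, phase))
        prev_phase = phase
        # end of this hom segment = start of the next segment (if any)
        last_hom_end = segs[i + 1][0] if i + 1 < len(segs) else None
    return out


def simulate_ssd_family(
    panel: FounderPanel,
    founder: "str | int",
    n_rils: int,
    n_generations: int,
    model: GenomeModel,
    modifiers: Sequence[ModifierSpec] = (),
    seed: int | None = None,
    family: str | None = None,
    partition: ArmPartition | None = None,
    ibd_intensity: float = 1.0,
) -> tuple[RILGenotypes, pd.DataFrame, pd.DataFrame]:
    """Simulate one biparental RIL family by single-seed descent.

    The F1 (common parent x founder) is selfed ``n_generations - 1`` times;
    ``n_generations = 7`` yields F7 lines with expected residual
    heterozygosity ``(1/2) ** 6`` per locus.  At every selfing meiosis the
    crossover intensity is scaled by the meiotic plant's current genotype at
    the modifier loci (heterozygous dosage 0.5).  ``ibd_intensity`` scales
    intensity within the founder's IBD tracts (sequence identity with the
    common parent locally favouring crossovers when > 1).

    Returns ``(genotypes, truth_crossovers, truth_per_ril)``:

    * genotypes — calls at the markers segregating between the two parents
      (A/B/H by origin);
    * truth_crossovers — ``(ril, chrom, pos_cm, phase_from, phase_to)`` for
      every observable junction of the final mosaic (het segments dropped);
    * truth_per_ril — per RIL: the observable phase-change count
      ``tco_true`` (what a dense noise-free genotype matrix would show),
      the haplotype-mosaic junction count ``junctions_true`` (mean of the
      two final haplotypes; the quantity whose density approaches the
      Haldane–Waterman limit of 2 per Morgan — slightly above ``tco_true``
      at finite generations because residual-heterozygous segments mask
      some phase changes), per-chromosome counts ``co_<chrom>``, and the
      final dosage of each modifier ``dosage_<k>``.
    """
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2 (the F1 is selfed onward)")
    _validate_modifiers(model, modifiers)
    rng = np.random.default_rng(seed)
    fi = panel.founder_index(founder) if isinstance(founder, str) else int(founder)
    fname = panel.founders[fi]
    if partition is None:
        partition = ArmPartition.from_model(model)

    # carrier lookup by origin code (0 = common parent, 1 = alt founder)
    carrier_by_origin = [
        (panel.common_parent in m.carriers, fname in m.carriers) for m in modifiers
    ]

    # IBD intensity regions for this founder (merged into modifier regions below)
    ibd_regions: dict[str, list[tuple[float, float]]] = {}
    if ibd_intensity != 1.0 and len(panel.ibd_tracts):
        sub = panel.ibd_tracts[panel.ibd_tracts["founder"] == fname]
        for _, r in sub.iterrows():
            ibd_regions.setdefault(r["chrom"], []).append((r["start_cm"], r["end_cm"]))

    off = _marker_offsets(model)
    final: list[dict[str, tuple[Hap, Hap]]] = []
    dosage_rows = []
    for _ in range(n_rils):
        geno: dict[str, tuple[Hap, Hap]] = {
            c.name: (
                (np.array([0.0]), np.array([0], dtype=np.int8)),
                (np.array([0.0]), np.array([1], dtype=np.int8)),
            )
            for c in model.chromosomes
        }
        for _gen in range(n_generations - 1):
            dos = [
                _modifier_dosage(geno, m, carrier_by_origin[k])
                for k, m in enumerate(modifiers)
            ]
            intensity = _modifier_regions(model, modifiers, dos, partition)
            intensity = _apply_ibd_boost(intensity, ibd_regions, ibd_intensity, model)
            g1, _ = simulate_meiosis(geno, model, intensity, rng=rng)
            g2, _ = simulate_meiosis(geno, model, intensity, rng=rng)
            geno = {c: (g1[c], g2[c]) for c in g1}
        final.append(geno)
        dosage_rows.append(
            [
                _modifier_dosage(geno, m, carrier_by_origin[k])
                for k, m in enumerate(modifiers)
            ]
        )

    # segregating markers: founder allele differs from the common parent
    seg_mask = panel.alleles[fi] != panel.alleles[0]
    marker_ids: list[str] = []
    marker_chrom: list[str] = []
    marker_pos: list[np.ndarray] = []
    for c in model.chromosomes:
        lo, hi = off[c.name]
        sel = seg_mask[lo:hi]
        ids = np.asarray(model.marker_ids(c.name))[sel]
        marker_ids.extend(ids.tolist())
        marker_chrom.extend([c.name] * int(sel.sum()))
        marker_pos.append(model.markers[c.name][sel])

    rils = [f"RIL{i + 1:04d}" for i in range(n_rils)]
    n_mark = len(marker_ids)
    calls = np.empty((n_mark, n_rils), dtype=np.int8)
    co_rows = []
    truth_rows = []
    for r, geno in enumerate(final):
        row0 = 0
        counts: dict[str, int] = {}
        for ci, c in enumerate(model.chromosomes):
            pos = marker_pos[ci]
            h0, h1 = geno[c.name]
            o0 = h0[1][np.searchsorted(h0[0], pos, side="right") - 1]
            o1 = h1[1][np.searchsorted(h1[0], pos, side="right") - 1]
            dos = o0.astype(np.int16) + o1
            col = np.where(dos == 0, codes.P1, np.where(dos == 2, codes.P2, codes.HET))
            calls[row0 : row0 + len(pos), r] = col
            row0 += len(pos)
            jx = _diploid_junctions(h0, h1)
            counts[c.name] = len(jx)
            for p, f_, t_ in jx:
                co_rows.append(
                    {
                        "ril": rils[r],
                        "chrom": c.name,
                        "pos_cm": p,
                        "phase_from": f_,
                        "phase_to": t_,
                    }
                )
        hap_j = 0.0
        for c in model.chromosomes:
            h0, h1 = geno[c.name]
            hap_j += ((len(h0[0]) - 1) + (len(h1[0]) - 1)) / 2.0
        rec = {"ril": rils[r], "tco_true": sum(counts.values()), "junctions_true": hap_j}
        rec.update({f"co_{k}": v for k, v in counts.items()})
        rec.update({f"dosage_{k}": d for k, d in enumerate(dosage_rows[r])})
        truth_rows.append(rec)

    fam = family or f"NAMx{fname}"
    genos = RILGenotypes(
        family=fam,
        common_parent=panel.common_parent,
        alt_parent=fname,
        markers=marker_ids,
        rils=rils,
        calls=calls,
    )
    truth_cos = pd.DataFrame(
        co_rows, columns=["ril", "chrom", "pos_cm", "phase_from", "phase_to"]
    )
    truth = pd.DataFrame(truth_rows)
    return genos, truth_cos, truth


def _apply_ibd_boost(
    intensity: "float | dict[str, list[tuple[float, float, float]]]",
    ibd_regions: dict[str, list[tuple[float, float]]],
    boost: float,
    model: GenomeModel,
) -> "float | dict[str, list[tuple[float, float, float]]]":
    if not ibd_regions or boost == 1.0:
        return intensity
    out: dict[str, list[tuple[float, float, float]]] = {}
    for c in model.chromosomes:
        if isinstance(intensity, dict):
            base_regions = intensity.get(c.name, [(0.0, c.length_cm, 1.0)])
        else:
            base_regions = [(0.0, c.length_cm, float(intensity))]
        tracts = _merge_intervals(ibd_regions.get(c.name, []))
        if not tracts:
            out[c.name] = list(base_regions)
            continue
        cuts = sorted({0.0, c.length_cm}
                      | {p for s, e, _ in base_regions for p in (s, e)}
                      | {p for s, e in tracts for p in (s, e)})
        pieces = []
        for s, e in zip(cuts[:-1], cuts[1:]):
            if e <= s:
                continue
            mid = (s + e) / 2
            m = next(mm for ss, ee, mm in base_regions if ss <= mid < ee)
            if any(ss <= mid < ee for ss, ee in tracts):
                m *= boost
            pieces.append((s, e, m))
        out[c.name] = pieces
    return out


# ---------------------------------------------------------------------------
# noise, annotation, helpers


def add_genotyping_noise(
    genos: RILGenotypes,
    error_rate: float,
    missing_rate: float,
    seed: int | None = None,
) -> RILGenotypes:
    """Flip each homozygous call with ``error_rate`` (A <-> B) and mask each
    non-missing call with ``missing_rate``, independently.  Zero rates return
    an identical matrix."""
    for name, r in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = genos.calls.copy()
    hom = (calls == codes.P1) | (calls == codes.P2)
    if error_rate > 0:
        flip = hom & (rng.random(calls.shape) < error_rate)
        calls[flip] = codes.P2 + codes.P1 - calls[flip]
    if missing_rate > 0:
        mask = (calls != codes.MISSING) & (rng.random(calls.shape) < missing_rate)
        calls[mask] = codes.MISSING
    return RILGenotypes(
        family=genos.family,
        common_parent=genos.common_parent,
        alt_parent=genos.alt_parent,
        markers=list(genos.markers),
        rils=list(genos.rils),
        calls=calls,
    )


def simulate_annotation(
    bins: pd.DataFrame,
    enrichment_odds: float,
    n_snps: int,
    seed: int | None = None,
    base_rate: float = 0.05,
) -> pd.DataFrame:
    """Draw a SNP annotation table with deleterious enrichment in
    low-recombination bins.

    ``bins`` must carry ``chrom``, ``bin`` and boolean ``high_recomb``
    columns (see :func:`namrecomb.genome_load.define_high_recomb_regions`).
    SNPs are spread uniformly over bins; in high-recombination bins a SNP is
    deleterious with probability ``base_rate``, and in the remaining bins
    with the probability whose odds are ``enrichment_odds`` times larger.
    ``enrichment_odds = 1`` gives a uniform rate; values <= 0 are rejected.
    """
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    rng = np.random.default_rng(seed)
    cols = ["snp", "chrom", "bin", "deleterious"]
    if n_snps == 0 or len(bins) == 0:
        return pd.DataFrame(columns=cols)
    odds_high = base_rate / (1 - base_rate)
    odds_low = odds_high * enrichment_odds
    p_low = odds_low / (1 + odds_low)
    idx = rng.integers(0, len(bins), n_snps)
    high = bins["high_recomb"].to_numpy()[idx]
    p = np.where(high, base_rate, p_low)
    dele = rng.random(n_snps) < p
    return pd.DataFrame(
        {
            "snp": [f"snp{i + 1:06d}" for i in range(n_snps)],
            "chrom": bins["chrom"].to_numpy()[idx],
            "bin": bins["bin"].to_numpy()[idx],
            "deleterious": dele.astype(int),
        }
    )


def divergent_panel(model: GenomeModel, n_founders: int = 2) -> FounderPanel:
    """A panel in which every founder differs from the common parent at every
    marker — all markers segregate in every family.  Useful for crossover-
    caller studies where full marker informativeness is wanted."""
    n = model.n_markers
    alleles = np.zeros((n_founders, n), dtype=np.int8)
    alleles[1:, :] = 1
    founders = ["CP"] + [f"F{i:02d}" for i in range(1, n_founders)]
    return FounderPanel(
        founders=founders,
        alleles=alleles,
        ibd_tracts=pd.DataFrame(columns=["founder", "chrom", "start_cm", "end_cm"]),
    )


def realized_modifier_effect(
    panel: FounderPanel,
    founder: "str | int",
    model: GenomeModel,
    modifier: ModifierSpec,
    n_rils: int = 800,
    n_generations: int = 7,
    seed: int | None = None,
) -> float:
    """Measure the emergent RIL-level crossover-count effect of one modifier.

    Simulates a family and returns the difference in mean true junction count
    between RILs fixed for the high allele and RILs fixed for the low allele
    (the effect unit used when reporting QTL allele effects).
    """
    _, _, truth = simulate_ssd_family(
        panel, founder, n_rils, n_generations, model, [modifier], seed=seed
    )
    hi = truth.loc[truth["dosage_0"] == 1.0, "tco_true"]
    lo = truth.loc[truth["dosage_0"] == 0.0, "tco_true"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("not enough fixed RILs in either dosage class")
    return float(hi.mean() - lo.mean())


def calibrate_beta(
    panel: FounderPanel,
    founder: "str | int",
    model: GenomeModel,
    target_effect: float,
    scope: str = "global",
    chrom: str | None = None,
    pos_cm: float | None = None,
    carriers: Iterable[str] = ("F01",),
    n_rils: int = 800,
    seed: int | None = None,
) -> ModifierSpec:
    """Scale a modifier's ``beta`` so its measured RIL-level effect is close
    to ``target_effect`` crossovers.

    One pilot simulation at a probe beta measures the realized effect; beta
    is then scaled linearly (the effect is close to linear in beta over the
    working range).
    """
    chrom = chrom or model.chrom_names[0]
    c = model.chrom(chrom)
    pos = c.length_cm / 2 if pos_cm is None else pos_cm
    probe = 0.3
    spec = ModifierSpec(chrom=chrom, pos_cm=pos, beta=probe, scope=scope,
                        carriers=frozenset(carriers))
    eff = realized_modifier_effect(panel, founder, model, spec, n_rils=n_rils, seed=seed)
    beta = probe * target_effect / eff
    return ModifierSpec(chrom=chrom, pos_cm=pos, beta=beta, scope=scope,
                        carriers=frozenset(carriers))
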