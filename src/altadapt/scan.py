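"""Composite-of-multiple-signals (CMS) selection scan and candidate calling.

Combines four per-variant statistics (F_ST, allele-frequency difference,
iHS, XP-EHH) through their empirical p-values into

    CMS = -log10( p_FST * p_dAF * p_iHS * p_XPEHH ),

scans the genome in overlapping windows for clusters of extreme scores,
classifies variant effects (protein-changing / expression-regulating /
conserved) and applies the three candidate-adaptive-variant criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WINDOW_BP = 30_000
STEP_BP = 15_000
TOP_FRACTION = 0.01
REGION_FRACTION = 0.30
FST_MULTIPLIER = 5.0
AF_MARGIN = 0.10
CADD_CUTOFF = 15.0
GERP_CUTOFF = 2.0

#: Sequence-ontology consequence terms counted as protein-sequence-changing.
CPS_CONSEQUENCES = frozenset({
    "missense_variant",
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
})

KNOWN_CONSEQUENCES = CPS_CONSEQUENCES | {
    "synonymous_variant", "intron_variant", "intergenic_variant",
    "upstream_gene_variant", "downstream_gene_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant",
    "regulatory_region_variant", "non_coding_transcript_variant",
    "splice_region_variant", "stop_retained_variant", "TF_binding_site_variant",
}


@dataclass
class CandidateRegion:
    """Merged run of significant scan windows (0-based half-open bp)."""
    chromosome: str
    start: int
    end: int
    n_variants: int
    frac_significant: float


@dataclass
class VariantAnnotation:
    """Functional annotation of one variant, as consumed from a VEP-style table."""
    consequence: str
    cadd: float | None = None
    gerp: float | None = None
    sift: float | None = None
    polyphen: float | None = None
    eqtl: list = field(default_factory=list)  # (gene, tissue) pairs
    gene: str | None = None


@dataclass
class CandidateAGV:
    """A variant passing all three adaptive-candidate criteria."""
    variant_id: str
    position: int
    effect_class: str
    adaptive_allele: str
    cms: float
    fst: float
    freq_pop1: float
    freq_pop2: float
    gene: str | None = None


def empirical_p(values, direction: str = "high") -> np.ndarray:
    """Empirical p per value: fraction of the genome at least as extreme.

    ``direction`` is "high" (large values extreme), "low", or "absolute"
    (|value| large extreme). Ties share the larger p; p is bounded in
    [1/N, 1]. Missing (NaN) values get NaN p and do not enter N.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("empirical_p needs at least one non-missing value")
    v = values[ok]
    if direction == "low":
        v = -v
    elif direction == "absolute":
        v = np.abs(v)
    elif direction != "high":
        raise ValueError(f"unknown direction {direction!r}")
    order = np.sort(v)
    # count of values >= v[i], ties included
    ge = n - np.searchsorted(order, v, side="left")
    out = np.full(values.shape, np.nan)
    out[ok] = ge / n
    return out


def cms_score(p_fst, p_daf, p_ihs, p_xpehh) -> np.ndarray:
    """CMS = -sum of log10 empirical p over the four component tests.

    Any missing component leaves the variant's CMS missing; a p of zero
    or below is rejected (empirical p-values are bounded below by 1/N).
    """
    ps = [np.asarray(p, dtype=float) for p in (p_fst, p_daf, p_ihs, p_xpehh)]
    stacked = np.stack(ps)
    if np.any(stacked[np.isfinite(stacked)] <= 0) or np.any(
        stacked[np.isfinite(stacked)] > 1
    ):
        raise ValueError("p-values must lie in (0, 1]")
    with np.errstate(invalid="ignore"):
        cms = -np.log10(stacked).sum(axis=0)
    cms[~np.isfinite(stacked).all(axis=0)] = np.nan
    return cms


def cms_threshold(cms, top_fraction: float = TOP_FRACTION) -> float:
    """Score cut separating the genome-wide top fraction (ties included)."""
    vals = np.asarray(cms, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite CMS scores")
    return float(np.quantile(vals, 1 - top_fraction))


def window_scan(cms, positions, chromosome: str = "1", window: int = WINDOW_BP,
                step: int = STEP_BP, top_fraction: float = TOP_FRACTION,
                region_fraction: float = REGION_FRACTION,
                chrom_length: int | None = None) -> list[CandidateRegion]:
    """Windowed scan for clusters of top-tier CMS scores.

    Windows of ``window`` bp advance by ``step`` bp anchored at position 0.
    A window is flagged when strictly more than ``region_fraction`` of its
    variants carry a top-tier score (top ``top_fraction`` genome-wide,
    ties at the threshold included). Overlapping flagged windows merge
    into maximal candidate regions.
    """
    cms = np.asarray(cms, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    ok = np.isfinite(cms)
    if not ok.any():
        return []
    thr = cms_threshold(cms, top_fraction)
    top = ok & (cms >= thr)
    last = int(positions.max()) if chrom_length is None else chrom_length
    flagged = []
    start = 0
    while start <= last:
        end = start + window
        if chrom_length is not None:
            end = min(end, chrom_length)
        in_win = (positions >= start) & (positions < end) & ok
        n = int(in_win.sum())
        if n > 0 and top[in_win].sum() / n > region_fraction:
            flagged.append((start, end, n, top[in_win].sum() / n))
        start += step
    # merge overlapping / adjacent-overlapping flagged windows
    regions: list[CandidateRegion] = []
    for s, e, n, frac in flagged:
        if regions and s < regions[-1].end:
            r = regions[-1]
            new_mask = (positions >= r.start) & (positions < e) & ok
            regions[-1] = CandidateRegion(
                chromosome, r.start, max(r.end, e), int(new_mask.sum()),
                float(top[new_mask].sum() / max(int(new_mask.sum()), 1)),
            )
        else:
            regions.append(CandidateRegion(chromosome, s, e, n, float(frac)))
    return regions


def classify_effect(annotation: VariantAnnotation,
                    cadd_cutoff: float = CADD_CUTOFF,
                    gerp_cutoff: float = GERP_CUTOFF) -> str | None:
    """Assign the variant-effect class: CPS, RGE, UCE or None.

    Precedence follows the annotation funnel: protein-sequence-changing
    consequences first, then expression-regulating (eQTL) variants among
    the rest, then conserved-but-unknown (GERP > 2 or CADD > 15).
    """
    cons = annotation.consequence
    if cons in CPS_CONSEQUENCES:
        return "CPS"
    if cons not in KNOWN_CONSEQUENCES:
        log.warning("unknown consequence term %r treated as non-CPS", cons)
    if annotation.eqtl:
        return "RGE"
    if (annotation.gerp is not None and annotation.gerp > gerp_cutoff) or (
        annotation.cadd is not None and annotation.cadd > cadd_cutoff
    ):
        return "UCE"
    return None


def select_agvs(stats: pd.DataFrame, annotations: dict, regions,
                genome_mean_fst: float, eas_freqs: dict | None = None,
                top_fraction: float = TOP_FRACTION,
                fst_multiplier: float = FST_MULTIPLIER,
                af_margin: float = AF_MARGIN) -> list[CandidateAGV]:
    """Apply the three candidate-adaptive-variant criteria inside regions.

    ``stats`` needs columns: variant_id, position, cms, fst, freq_pop1,
    freq_pop2, and allele columns ref/alt. A variant is kept when it
    (1) carries a top-tier CMS score, (2) is strongly differentiated
    (F_ST strictly above ``fst_multiplier`` x genome mean, with pop1
    frequency differing from pop2 and from the East-Asian reference by
    more than ``af_margin``), and (3) has a non-empty effect class.
    The adaptive allele is whichever allele is more frequent in pop1.
    """
    thr = cms_threshold(stats["cms"].to_numpy(), top_fraction)
    out: list[CandidateAGV] = []
    for region in regions:
        sel = stats[(stats["position"] >= region.start) & (stats["position"] < region.end)]
        for _, row in sel.iterrows():
            if not np.isfinite(row["cms"]) or row["cms"] < thr:
                continue
            if not np.isfinite(row["fst"]) or row["fst"] <= fst_multiplier * genome_mean_fst:
                continue
            f1, f2 = row["freq_pop1"], row["freq_pop2"]
            if abs(f1 - f2) <= af_margin:
                continue
            vid = row["variant_id"]
            if eas_freqs is not None and vid in eas_freqs:
                if abs(f1 - eas_freqs[vid]) <= af_margin:
                    continue
            elif eas_freqs is not None:
                log.info("no East-Asian reference frequency for %s; "
                         "criterion evaluated on pop1 vs pop2 only", vid)
            ann = annotations.get(vid)
            if ann is None:
                continue
            effect = classify_effect(ann)
            if effect is None:
                continue
            adaptive = row.get("alt", "1") if f1 > f2 else row.get("ref", "0")
            out.append(CandidateAGV(
                variant_id=vid, position=int(row["position"]), effect_class=effect,
                adaptive_allele=str(adaptive), cms=float(row["cms"]),
                fst=float(row["fst"]), freq_pop1=float(f1), freq_pop2=float(f2),
                gene=ann.gene,
            ))
    # de-duplicate variants falling in two merged/overlapping regions
    seen, unique = set(), []
    for agv in out:
        if agv.variant_id not in seen:
            seen.add(agv.variant_id)
            unique.append(agv)
    return unique


def phenotype_hypothesis_count(n_variants: int, n_traits: int) -> int:
    """Size of the phenotype-association testing family (variants x traits)."""
    if n_variants < 0 or n_traits < 0:
        raise ValueError("counts must be non-negative")
    return n_variants * n_traits
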