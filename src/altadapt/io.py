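"""Formats, configuration, QC filters and the end-to-end pipeline.

Conventions: VCF positions are 1-based on disk and 0-based in memory;
BED output is 0-based half-open. The ancestral allele is taken from the
AA INFO field when present and haplotypes are repolarized so that 0 is
ancestral. Every stage of the pipeline logs its thresholds and a filter
funnel (kept + dropped = input).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import assoc as assoc_mod
from . import dating, fis, popgen, scan, simdata

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with published defaults."""

    vcf: str | None = None
    annotations: str | None = None
    phenotypes: str | None = None
    expression: str | None = None
    pop1: str = simdata.POP1
    pop2: str = simdata.POP2
    window_bp: int = scan.WINDOW_BP
    step_bp: int = scan.STEP_BP
    top_fraction: float = scan.TOP_FRACTION
    region_fraction: float = scan.REGION_FRACTION
    cadd_cutoff: float = scan.CADD_CUTOFF
    gerp_cutoff: float = scan.GERP_CUTOFF
    fst_multiplier: float = scan.FST_MULTIPLIER
    af_margin: float = scan.AF_MARGIN
    cis_window_bp: int = assoc_mod.CIS_WINDOW_BP
    prob_cutoff: float = anc.PROB_CUTOFF
    modern_quorum_fraction: float = anc.MODERN_QUORUM_FRACTION
    yri_ceiling_fraction: float = anc.YRI_CEILING_FRACTION
    maf_floor: float = popgen.MAF_FLOOR
    hwe_p: float = 1e-6
    max_missing: float = 0.20
    adjusted_p: float = assoc_mod.FDR_ALPHA
    generation_years: float = dating.GENERATION_YEARS
    t_humchimp: float = dating.T_HUMAN_CHIMP_YEARS
    seed: int = 1
    outdir: str = "altadapt_out"

    def __post_init__(self) -> None:
        for name in ("top_fraction", "region_fraction", "maf_floor",
                     "max_missing", "adjusted_p", "prob_cutoff",
                     "modern_quorum_fraction", "yri_ceiling_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if v is not None:
                    fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            t = types[key]
            if "int" in t:
                kwargs[key] = int(val)
            elif "float" in t:
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(hapset: popgen.HaplotypeSet, path, ref: str = "A",
              alt: str = "G") -> None:
    """Write a phased single-chromosome VCF (GT with '|', AA INFO field)."""
    n_ind = hapset.n_haplotypes // 2
    if hapset.n_haplotypes % 2:
        raise ValueError("odd haplotype count; cannot write diploid VCF")
    samples = []
    for i in range(n_ind):
        sid, _ = hapset.samples[2 * i]
        samples.append(sid)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={hapset.chromosome}>\n")
        fh.write("##population=" + ",".join(
            f"{s}:{p}" for s, p in zip(samples, hapset.populations[0::2])) + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(hapset.n_sites):
            info = f"AA={ref}" if hapset.polarized[j] else "."
            gts = []
            for i in range(n_ind):
                a, b = hapset.alleles[2 * i, j], hapset.alleles[2 * i + 1, j]
                gts.append(f"{'.' if a == popgen.MISSING else a}|"
                           f"{'.' if b == popgen.MISSING else b}")
            fh.write(f"{hapset.chromosome}\t{hapset.positions[j] + 1}\tvar{j}\t"
                     f"{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path, populations: dict | None = None) -> popgen.HaplotypeSet:
    """Read a phased VCF into a HaplotypeSet (biallelic SNVs only).

    1-based VCF positions become 0-based; when the AA INFO field names
    the ALT allele the site is repolarized so 0 = ancestral; sites
    without AA are flagged unpolarized. Multiallelic records are skipped
    with a counted warning; an unphased genotype is an error naming the
    record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    pop_map = dict(populations) if populations else {}
    cols, positions, polar = [], [], []
    chrom = None
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_multi += 1
            continue
        chrom = rec.CHROM
        gts = rec.genotypes  # [a, b, phased] per sample
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a, b, phased) in enumerate(gts):
            if not phased and a != b:
                raise ValueError(
                    f"unphased heterozygote at {rec.CHROM}:{rec.POS} "
                    f"sample {samples[i]}")
            hap[2 * i] = popgen.MISSING if a < 0 else a
            hap[2 * i + 1] = popgen.MISSING if b < 0 else b
        aa = rec.INFO.get("AA")
        if aa is not None and aa == rec.ALT[0]:
            swap = hap >= 0
            hap[swap] = 1 - hap[swap]
        positions.append(rec.POS - 1)
        polar.append(aa is not None)
        cols.append(hap)
    if n_multi:
        log.warning("skipped %d multiallelic/non-SNV records", n_multi)
    if not cols:
        raise ValueError("no usable biallelic SNVs in the VCF")
    # population labels from the ##population header line when present
    if not pop_map:
        for line in vcf.raw_header.splitlines():
            if line.startswith("##population="):
                for pair in line.split("=", 1)[1].split(","):
                    sid, _, pop = pair.partition(":")
                    pop_map[sid] = pop
    pops = []
    sample_pairs = []
    for s in samples:
        pops.extend([pop_map.get(s, "pop")] * 2)
        sample_pairs.extend([(s, 0), (s, 1)])
    return popgen.HaplotypeSet(
        alleles=np.column_stack(cols), positions=np.asarray(positions),
        chromosome=chrom, populations=np.asarray(pops), samples=sample_pairs,
        polarized=np.asarray(polar))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p (two-sided enumeration over het counts).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on allele counts.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or n_rare == 0:
        return 1.0
    # log-probability of each compatible het count (same parity as n_rare)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.empty(len(hets), dtype=float)
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = (
            math.lgamma(n + 1)
            - math.lgamma(h + 1) - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            + h * math.log(2)
            + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.flatnonzero(hets == n_het)[0]
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def qc_filter(hapset: popgen.HaplotypeSet, hwe_p: float = 1e-6,
              max_missing: float = 0.20):
    """Drop variants failing HWE (within any population) or missingness.

    Returns (filtered HaplotypeSet, report dict). The exact HWE test runs
    per population on diploid genotypes (consecutive haplotype pairs).
    """
    n_sites = hapset.n_sites
    keep = np.ones(n_sites, dtype=bool)
    n_missing_fail = n_hwe_fail = 0
    missing_rate = (hapset.alleles == popgen.MISSING).mean(axis=0)
    for j in range(n_sites):
        if missing_rate[j] > max_missing:
            keep[j] = False
            n_missing_fail += 1
            continue
        for pop in pd.unique(hapset.populations):
            sub = hapset.alleles[hapset.populations == pop, j]
            a, b = sub[0::2], sub[1::2]
            ok = (a != popgen.MISSING) & (b != popgen.MISSING)
            g = a[ok] + b[ok]
            het, hom0, hom2 = int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum())
            if hwe_exact_p(het, hom0, hom2) < hwe_p:
                keep[j] = False
                n_hwe_fail += 1
                break
    report = {"input": n_sites, "kept": int(keep.sum()),
              "dropped_missing": n_missing_fail, "dropped_hwe": n_hwe_fail}
    log.info("qc_filter: %s", report)
    return hapset.subset(site_mask=keep), report


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def compute_selection_stats(hapset: popgen.HaplotypeSet, config: PipelineConfig) -> pd.DataFrame:
    """Per-variant F_ST, dAF, iHS, XP-EHH, empirical p-values and CMS."""
    h1 = hapset.population(config.pop1)
    h2 = hapset.population(config.pop2)
    d1, d2 = h1.dosage(), h2.dosage()

    def geno_counts(d):
        return np.stack([(d == 0).sum(axis=0), (d == 1).sum(axis=0),
                         (d == 2).sum(axis=0)], axis=1)

    fst = popgen.weir_cockerham_fst(geno_counts(d1), geno_counts(d2))
    f1, f2 = h1.derived_freq(), h2.derived_freq()
    daf = popgen.delta_af(np.nan_to_num(f1), np.nan_to_num(f2))
    daf[~(np.isfinite(f1) & np.isfinite(f2))] = np.nan
    # short synthetic regions clip most EHH integrals at the edge; keep them
    ihs_std, _, _ = popgen.ihs_scan(h1, maf_floor=config.maf_floor,
                                    exclude_truncated=False)
    xpe_std, _, _ = popgen.xpehh_scan(h1, h2, maf_floor=config.maf_floor,
                                      exclude_truncated=False)

    p_fst = scan.empirical_p(fst, "high")
    p_daf = scan.empirical_p(daf, "high")
    p_ihs = scan.empirical_p(ihs_std, "absolute")
    p_xpe = scan.empirical_p(xpe_std, "high")
    cms = scan.cms_score(p_fst, p_daf, p_ihs, p_xpe)
    return pd.DataFrame({
        "variant_id": [f"var{j}" for j in range(hapset.n_sites)],
        "chromosome": hapset.chromosome,
        "position": hapset.positions,
        "fst": fst, "delta_af": daf, "ihs": ihs_std, "xpehh": xpe_std,
        "p_fst": p_fst, "p_daf": p_daf, "p_ihs": p_ihs, "p_xpehh": p_xpe,
        "cms": cms,
        "freq_pop1": f1, "freq_pop2": f2,
        "ref": "A", "alt": "G",
    })


def run_pipeline(config: PipelineConfig, sim_config=None) -> dict:
    """Execute simulate -> stats -> scan -> prioritize -> assoc -> date.

    With no input VCF configured, data come from the bundled generator
    (``sim_config`` or its defaults). Writes every intermediate table
    under ``config.outdir`` plus a JSON run manifest; returns the result
    bundle in memory. Any stage failure aborts with the stage name;
    partial outputs stay on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "thresholds": {
        f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        if isinstance(getattr(config, f.name), (int, float))}}
    bundle = {}
    stage = "simulate"
    try:
        if config.vcf:
            hapset = read_vcf(config.vcf)
            truth = None
        else:
            sim_config = sim_config or simdata.SimulationConfig(seed=config.seed)
            hapset, truth = simdata.simulate_split_populations(sim_config)
            write_vcf(hapset, outdir / "haplotypes.vcf")
        bundle["hapset"], bundle["truth"] = hapset, truth
        manifest["stages"].append(stage)

        stage = "qc"
        focal_pos = (bundle["hapset"].positions[truth.focal_index]
                     if truth is not None else None)
        hapset, qc_report = qc_filter(hapset, config.hwe_p, config.max_missing)
        # scan family restricted to common variants (pooled MAF above floor)
        freq = hapset.derived_freq()
        maf_ok = np.minimum(freq, 1 - freq) > config.maf_floor
        qc_report["dropped_maf"] = int((~maf_ok).sum())
        qc_report["kept"] = int(maf_ok.sum())
        hapset = hapset.subset(site_mask=maf_ok)
        manifest["qc"] = qc_report
        if truth is not None:
            truth.focal_index = int(np.searchsorted(hapset.positions, focal_pos))
        bundle["hapset_qc"] = hapset
        manifest["stages"].append(stage)

        stage = "stats"
        stats = compute_selection_stats(hapset, config)
        stats.to_csv(outdir / "stats.tsv", sep="\t", index=False)
        bundle["stats"] = stats
        manifest["stages"].append(stage)

        stage = "scan"
        regions = scan.window_scan(
            stats["cms"].to_numpy(), stats["position"].to_numpy(),
            chromosome=hapset.chromosome, window=config.window_bp,
            step=config.step_bp, top_fraction=config.top_fraction,
            region_fraction=config.region_fraction)
        with open(outdir / "regions.bed", "w") as fh:
            for r in regions:
                fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t"
                         f"{r.n_variants}\t{r.frac_significant:.4f}\n")
        bundle["regions"] = regions
        manifest["n_regions"] = len(regions)
        manifest["stages"].append(stage)

        stage = "annotate"
        if config.annotations:
            ann_df = pd.read_csv(config.annotations, sep="\t")
        elif truth is not None:
            ann_df = simdata.simulate_annotations(hapset, truth, seed=config.seed)
        else:
            raise RuntimeError("no annotation table available")
        annotations = {
            row.variant_id: scan.VariantAnnotation(
                consequence=row.consequence, cadd=row.cadd, gerp=row.gerp,
                eqtl=[tuple(e.split(":")) for e in str(row.eqtl).split(";")
                      if e and e != "nan"],
                gene=row.gene)
            for row in ann_df.itertuples()}
        bundle["annotations"] = annotations
        manifest["stages"].append(stage)

        stage = "select_agvs"
        mean_fst = float(np.nanmean(stats["fst"]))
        agvs = scan.select_agvs(stats, annotations, regions, mean_fst,
                                top_fraction=config.top_fraction,
                                fst_multiplier=config.fst_multiplier,
                                af_margin=config.af_margin)
        agv_df = pd.DataFrame([dataclasses.asdict(a) for a in agvs])
        agv_df.to_csv(outdir / "agvs.tsv", sep="\t", index=False)
        bundle["agvs"] = agvs
        manifest["n_agvs"] = len(agvs)
        manifest["stages"].append(stage)

        stage = "prioritize"
        if agvs:
            ann_idx = ann_df.set_index("variant_id")
            rows = []
            for a in agvs:
                rows.append({
                    "variant_id": a.variant_id, "position": a.position,
                    "delta_af": a.freq_pop1 - a.freq_pop2,
                    "effect_class": a.effect_class, "cms": a.cms,
                    "gene": a.gene,
                    "cadd": ann_idx.loc[a.variant_id, "cadd"],
                    "gerp": ann_idx.loc[a.variant_id, "gerp"],
                })
            fis_table = fis.build_fis_table(pd.DataFrame(rows))
            gene_rank = fis.prioritize_genes(fis_table)
            gene_rank.to_csv(outdir / "gene_rank.tsv", sep="\t", index=False)
            bundle["gene_rank"] = gene_rank
        manifest["stages"].append(stage)

        stage = "date"
        if truth is not None and agvs:
            h1 = hapset.population(config.pop1)
            carriers = h1.alleles[:, truth.focal_index] == 1
            if carriers.sum() >= 2:
                d_anc = sim_config.mutation_rate * sim_config.region_length_bp \
                    * config.t_humchimp / sim_config.generation_years
                est = dating.date_haplotype_class(
                    h1, carriers, d_anc=d_anc,
                    l_ab=sim_config.region_length_bp,
                    t_humchimp=config.t_humchimp,
                    p0=truth.true_p0, pt=truth.true_pt,
                    t_generations=sim_config.split_generations)
                pd.DataFrame([dataclasses.asdict(est)]).to_csv(
                    outdir / "dating.tsv", sep="\t", index=False)
                bundle["dating"] = est
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    with open(outdir / "run.log", "w") as fh:
        for k, v in manifest["thresholds"].items():
            fh.write(f"{k} = {v}\n")
        for k in ("qc", "n_regions", "n_agvs"):
            if k in manifest:
                fh.write(f"{k} = {manifest[k]}\n")
    bundle["manifest"] = manifest
    return bundle


def write_copy_tensor(tensor: anc.CopyProbabilityTensor, path) -> None:
    """Long-format TSV: run, donor, haplotype, site, probability."""
    R, D, K, L = tensor.P.shape
    with open(path, "w") as fh:
        fh.write("run\tdonor\thaplotype\tsite\tprobability\n")
        for i in range(R):
            for j in range(D):
                for k in range(K):
                    for l in range(L):
                        fh.write(f"{i}\t{tensor.donors[j]}\t{k}\t{l}\t"
                                 f"{tensor.P[i, j, k, l]:.6g}\n")


def read_copy_tensor(path) -> anc.CopyProbabilityTensor:
    """Read the long-format tensor TSV back into dense form."""
    df = pd.read_csv(path, sep="\t")
    donors = tuple(pd.unique(df["donor"]))
    R = df["run"].max() + 1
    K = df["haplotype"].max() + 1
    L = df["site"].max() + 1
    P = np.zeros((R, len(donors), K, L))
    didx = {d: j for j, d in enumerate(donors)}
    P[df["run"], df["donor"].map(didx), df["haplotype"], df["site"]] = df["probability"]
    return anc.CopyProbabilityTensor(P=P, donors=donors)
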