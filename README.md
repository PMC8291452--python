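# altadapt

Tools for detecting and characterizing positive selection in high-altitude
human populations: a composite selection scan over phased genomes of a
highland population (TIB) and a lowland reference (HAN), candidate-variant
filtering and functional prioritization, phenotype/eQTL association with
epistasis modeling, archaic local-ancestry calling from chromosome-painting
output, and coalescent dating of adaptive haplotypes with deterministic
selection-coefficient estimation. A bundled synthetic-data generator with
known ground truth makes every stage testable without access to restricted
cohort data.

## The statistics at the core

**Composite selection scan.** For each biallelic SNV with minor allele
frequency > 0.05 and known ancestral state, four statistics are computed:
Weir–Cockerham *F*<sub>ST</sub> between the two populations, the
allele-frequency difference ΔAF = *f*<sub>TIB</sub> − *f*<sub>HAN</sub>,
the integrated haplotype score iHS within the highland population, and
XP-EHH with the lowland population as reference. Each is converted to an
empirical *p*-value and combined as

    CMS = −log₁₀ ∏ᵢ pᵢ

Overlapping 30-kb windows (15-kb step) are flagged when more than 30% of
their variants carry top-tier CMS scores; merged flagged windows form
candidate regions. Candidate adaptive variants inside those regions must
(1) carry a top-tier CMS score, (2) show *F*<sub>ST</sub> above 5× the
genome-wide mean with clearly different allele frequencies between the
populations, and (3) have an assignable biological effect: protein-sequence
changing (CPS), expression-regulating (RGE, eQTL evidence), or conserved
with unknown function (UCE; GERP > 2 or CADD > 15).

**Functional prioritization.** Per annotation method *i* (CADD, GERP), each
candidate gets a functional importance score *FIS*ᵢ = *CS*ᵢ × |ΔAF| —
negative GERP scores floored to 0, CPS/RGE variants assigned the maximum
conservation score — and genes are ranked by the mean FIS rank of their
best candidate variant.

**Archaic ancestry.** Given copy probabilities *P*ᵢⱼₖₗ from replicated
chromosome painting against a five-donor panel (Denisovan, Neanderthal,
Ust'-Ishim, Han, Yoruba), each (haplotype, site) counts the runs where a
donor's probability exceeds 0.8. A modern donor is called when it holds
the overall maximum count above a 10%-of-runs quorum; an archaic donor
when it clears the quorum while African support stays at or below 1% of
runs and combined modern support at or below the quorum (421 and 42 runs
with the published 4,212-run panel); otherwise the site is Uncertain.

**Dating and selection strength.** The age of an adaptive haplotype class
is TMRCA = π̄ / (2 μ<sub>ab</sub> *l*<sub>ab</sub>), with the local
mutation rate calibrated against the human–chimp ancestor
(μ<sub>ab</sub> = *d* / (*l*<sub>ab</sub> · 13 My)). The selection
coefficient follows the deterministic additive sweep model

    s = (1/t) · log₁₀[ p_t(1−p₀) / (p₀(1−p_t)) ]

and the synthetic generator's sweep trajectory uses the same log₁₀-odds
recurrence, so the estimator inverts the simulation exactly.

## Worked example

```python
import altadapt as aa

# Selection coefficient of the key highland missense variant from its
# observed carrier frequencies (2/78 lowland, 58/76 highland) at the two
# population-divergence endpoints:
print(f"s(t=360) = {aa.selection_coefficient(2/78, 58/76, 360):.4f}")
print(f"s(t=600) = {aa.selection_coefficient(2/78, 58/76, 600):.4f}")

# End-to-end scan on a synthetic sweep (200-kb region, s = 0.0042,
# desk-scale significance tier = sweep span / region length):
cfg = aa.PipelineConfig(seed=1, outdir="out", top_fraction=0.15)
bundle = aa.run_pipeline(cfg)
for r in bundle["regions"]:
    print(f"  region {r.chromosome}:{r.start}-{r.end}  "
          f"({r.n_variants} variants, {r.frac_significant:.0%} top-tier)")
for a in bundle["agvs"]:
    print(f"  candidate {a.variant_id} pos={a.position} class={a.effect_class} "
          f"CMS={a.cms:.2f} F_ST={a.fst:.2f} "
          f"freqs {a.freq_pop1:.2f}/{a.freq_pop2:.2f}")
est = bundle["dating"]
print(f"  TMRCA of adaptive-allele carriers: {est.tmrca_years:.0f} "
      f"+/- {est.tmrca_sd_years:.0f} years (n={est.n} haplotypes)")
print(f"  recovered s = "
      f"{aa.selection_coefficient(est.p0, est.pt, est.t_generations):.4f}")
```

prints

```
s(t=360) = 0.0058
s(t=600) = 0.0035
  region 1:75000-120000  (9 variants, 44% top-tier)
  candidate var20 pos=101826 class=CPS CMS=3.90 F_ST=0.72 freqs 0.76/0.03
  TMRCA of adaptive-allele carriers: 49907 +/- 27037 years (n=61 haplotypes)
  recovered s = 0.0042
```

The implanted sweep variant is recovered as a protein-sequence-changing
candidate inside the single detected region: its highland/lowland
frequencies (0.76/0.03) mirror the scenario the generator emulates, and
the deterministic estimator returns the generator's true *s* exactly.

The same stages are available from the shell:

```bash
altadapt simulate --seed 1 --out sim/
altadapt stats sim/haplotypes.vcf --out stats.tsv
altadapt scan stats.tsv --top-fraction 0.15 --out regions.bed
altadapt run --seed 1 --outdir out/
```

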