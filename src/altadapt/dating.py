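"""Haplotype-class dating and deterministic selection-coefficient estimation.

The age of a haplotype class (e.g. carriers of an adaptive allele) is
estimated from its mean pairwise nucleotide differences pi-bar as

    TMRCA = pi_bar / (2 * mu_ab * l_ab)

with the regional mutation rate mu_ab calibrated against the
human-chimpanzee ancestor: mu_ab = d / (l_ab * T_split) where d is the
human-ancestor difference count over the region and T_split the
human-chimp divergence time (13 My by default).

The selection coefficient of a rising adaptive allele comes from the
deterministic additive sweep model in log10-odds form:

    s = (1/t) * log10[ p_t (1 - p_0) / (p_0 (1 - p_t)) ]

with p_0 the initial and p_t the current allele frequency after t
generations. Two timing scenarios are supported: selection starting at
the population split (p_0 = lowland frequency), or at introgression of
the allele (p_0 = 1 / 2 Ne, t from the haplotype TMRCA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .popgen import HaplotypeSet, mean_pairwise_diff

T_HUMAN_CHIMP_YEARS = 13e6
GENERATION_YEARS = 25.0


@dataclass
class CoalescentEstimate:
    """Dating and sweep-strength summary for one haplotype class."""
    pi_bar: float
    n: int
    l_ab: int
    mu_ab: float
    tmrca_years: float
    tmrca_sd_years: float | None = None
    p0: float | None = None
    pt: float | None = None
    t_generations: float | None = None
    s: float | None = None


def local_mutation_rate(d_anc: float, l_ab: int,
                        t_humchimp: float = T_HUMAN_CHIMP_YEARS) -> float:
    """Per-site per-year mutation rate calibrated on the region.

    d_anc: differences between the reference and the human-chimp ancestor
    over the region; l_ab: region length in sites; t_humchimp: divergence
    time in years.
    """
    if l_ab <= 0:
        raise ValueError("region length must be positive")
    if d_anc < 0:
        raise ValueError("difference count cannot be negative")
    return d_anc / (l_ab * t_humchimp)


def tmrca(pi_bar: float, mu_ab: float, l_ab: int) -> float:
    """TMRCA in years: pi_bar / (2 * mu_ab * l_ab).

    Returns NaN (flagged undefined) when the mutation rate is zero.
    """
    if mu_ab < 0:
        raise ValueError("mutation rate cannot be negative")
    if mu_ab == 0:
        return float("nan")
    return pi_bar / (2.0 * mu_ab * l_ab)


def tmrca_with_dispersion(hapset: HaplotypeSet, mu_ab: float, l_ab: int,
                          site_mask=None) -> tuple[float, float]:
    """TMRCA plus its dispersion over pairwise differences.

    The dispersion is the standard deviation of per-pair estimates
    pi_ij / (2 * mu_ab * l_ab) over all haplotype pairs.
    """
    alleles = hapset.alleles if site_mask is None else hapset.alleles[:, site_mask]
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if mu_ab == 0:
        return float("nan"), float("nan")
    pair_diffs = []
    for i in range(n - 1):
        a = alleles[i]
        rest = alleles[i + 1:]
        both = (a != -1) & (rest != -1)
        pair_diffs.extend(((a != rest) & both).sum(axis=1).tolist())
    pair_t = np.asarray(pair_diffs, dtype=float) / (2.0 * mu_ab * l_ab)
    return float(pair_t.mean()), float(pair_t.std(ddof=1)) if len(pair_t) > 1 else 0.0


def selection_coefficient(p0: float, pt: float, t_generations: float) -> float:
    """Deterministic additive-sweep s from start/end allele frequencies."""
    if not (0 < p0 < 1) or not (0 < pt < 1):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if t_generations <= 0:
        raise ValueError("generations must be positive")
    return math.log10(pt * (1 - p0) / (p0 * (1 - pt))) / t_generations


def years_to_generations(years: float, generation_years: float = GENERATION_YEARS) -> float:
    """Convert calendar years to generations."""
    if generation_years <= 0:
        raise ValueError("generation time must be positive")
    if years < 0:
        raise ValueError("years cannot be negative")
    return years / generation_years


def introgression_scenario_s(pt: float, ne: float, tmrca_years: float,
                             generation_years: float = GENERATION_YEARS) -> float:
    """s assuming selection began at introgression: p0 = 1/2Ne, t = TMRCA."""
    if ne <= 0:
        raise ValueError("effective size must be positive")
    p0 = 1.0 / (2.0 * ne)
    t = years_to_generations(tmrca_years, generation_years)
    return selection_coefficient(p0, pt, t)


def date_haplotype_class(hapset: HaplotypeSet, carrier_mask, d_anc: float,
                         l_ab: int, t_humchimp: float = T_HUMAN_CHIMP_YEARS,
                         p0: float | None = None, pt: float | None = None,
                         t_generations: float | None = None) -> CoalescentEstimate:
    """Full dating of a haplotype class, optionally with a sweep estimate.

    ``carrier_mask`` selects the class (e.g. adaptive-allele carriers,
    optionally restricted to a marker set); ``d_anc`` and ``l_ab``
    calibrate the local mutation rate.
    """
    cls = hapset.subset(haplotype_mask=carrier_mask)
    mu = local_mutation_rate(d_anc, l_ab, t_humchimp)
    pi = mean_pairwise_diff(cls)
    if mu > 0:
        t_est, t_sd = tmrca_with_dispersion(cls, mu, l_ab)
    else:
        t_est, t_sd = float("nan"), float("nan")
    s = None
    if p0 is not None and pt is not None and t_generations is not None:
        s = selection_coefficient(p0, pt, t_generations)
    return CoalescentEstimate(
        pi_bar=pi, n=cls.n_haplotypes, l_ab=l_ab, mu_ab=mu,
        tmrca_years=t_est, tmrca_sd_years=t_sd,
        p0=p0, pt=pt, t_generations=t_generations, s=s,
    )
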