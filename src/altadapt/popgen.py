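"""Per-variant and per-haplotype population-genetic statistics.

Implements the building blocks of a two-population selective-sweep scan:
Weir-Cockerham F_ST, allele-frequency differences, extended haplotype
homozygosity (EHH) and its integrated scores iHS and XP-EHH, pairwise LD
r-squared, and mean pairwise nucleotide differences (pi-bar).

Haplotypes are held in a :class:`HaplotypeSet`: a haplotype x site matrix
over {0, 1, -1} where 0 is the ancestral allele, 1 the derived allele and
-1 missing. Missing alleles are treated conservatively: they break
haplotype identity in EHH comparisons (a missing allele matches nothing,
not even another missing allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

#: EHH level below which the iHH integral is truncated.
EHH_CUTOFF = 0.05
#: Minor-allele-frequency floor for iHS / XP-EHH scans.
MAF_FLOOR = 0.05
#: Width of the derived-allele-frequency bins used to standardize iHS.
IHS_BIN_WIDTH = 0.02
#: Minimum number of scores per standardization bin; sparser bins are merged.
IHS_BIN_MIN = 10


@dataclass
class HaplotypeSet:
    """Phased haplotypes with positions, polarity and population labels.

    Parameters
    ----------
    alleles
        int8 matrix of shape (n_haplotypes, n_sites) over {0, 1, -1};
        0 = ancestral where ``polarized``.
    positions
        0-based base-pair coordinates, strictly increasing.
    chromosome
        Chromosome identifier.
    populations
        Per-haplotype population label, length n_haplotypes.
    samples
        Per-haplotype ``(sample_id, phase_index)`` pairs.
    polarized
        Per-site flag; False where the ancestral state is unknown.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chromosome: str
    populations: np.ndarray
    samples: list[tuple[str, int]] = field(default_factory=list)
    polarized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.populations = np.asarray(self.populations)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a haplotype x site matrix")
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions length must equal number of sites")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.populations.shape[0] != self.alleles.shape[0]:
            raise ValueError("every haplotype needs a population label")
        if self.polarized is None:
            self.polarized = np.ones(self.alleles.shape[1], dtype=bool)
        if not self.samples:
            self.samples = [(f"S{i // 2}", i % 2) for i in range(self.alleles.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def subset(self, haplotype_mask=None, site_mask=None) -> "HaplotypeSet":
        hmask = np.ones(self.n_haplotypes, bool) if haplotype_mask is None else np.asarray(haplotype_mask)
        smask = np.ones(self.n_sites, bool) if site_mask is None else np.asarray(site_mask)
        if hmask.dtype != bool:
            tmp = np.zeros(self.n_haplotypes, bool)
            tmp[hmask] = True
            hmask = tmp
        if smask.dtype != bool:
            tmp = np.zeros(self.n_sites, bool)
            tmp[smask] = True
            smask = tmp
        return HaplotypeSet(
            alleles=self.alleles[hmask][:, smask],
            positions=self.positions[smask],
            chromosome=self.chromosome,
            populations=self.populations[hmask],
            samples=[s for s, keep in zip(self.samples, hmask) if keep],
            polarized=self.polarized[smask],
        )

    def population(self, label: str) -> "HaplotypeSet":
        return self.subset(haplotype_mask=self.populations == label)

    def derived_freq(self) -> np.ndarray:
        """Per-site derived-allele frequency over non-missing haplotypes."""
        called = self.alleles != MISSING
        n = called.sum(axis=0)
        der = (self.alleles == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, der / np.maximum(n, 1), np.nan)

    def dosage(self) -> np.ndarray:
        """Diploid dosage matrix (n_individuals x n_sites), pairing phases.

        Any missing allele makes the individual's dosage missing (NaN).
        """
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count; cannot pair into diploids")
        a = self.alleles.astype(float)
        a[self.alleles == MISSING] = np.nan
        return a[0::2] + a[1::2]


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST (two populations)
# ---------------------------------------------------------------------------

def weir_cockerham_fst(counts1, counts2):
    """Two-population Weir-Cockerham (1984) theta per variant.

    Parameters
    ----------
    counts1, counts2
        Genotype counts per population, arrays of shape (n_variants, 3)
        giving (hom-ref, het, hom-alt) counts of genotyped individuals.

    Returns
    -------
    theta : ndarray
        a / (a + b + c) per variant; NaN where the denominator is zero
        (e.g. sites monomorphic in both populations) or where a population
        has fewer than two genotyped individuals.
    """
    counts1 = np.atleast_2d(np.asarray(counts1, dtype=float))
    counts2 = np.atleast_2d(np.asarray(counts2, dtype=float))
    r = 2.0
    n1 = counts1.sum(axis=1)
    n2 = counts2.sum(axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    n1s = np.where(valid, n1, 2.0)  # placeholder to avoid divide warnings
    n2s = np.where(valid, n2, 2.0)

    p1 = (2 * counts1[:, 2] + counts1[:, 1]) / (2 * n1s)
    p2 = (2 * counts2[:, 2] + counts2[:, 1]) / (2 * n2s)
    h1 = counts1[:, 1] / n1s  # observed heterozygosity
    h2 = counts2[:, 1] / n2s

    nbar = (n1s + n2s) / r
    nc = (r * nbar - (n1s**2 + n2s**2) / (r * nbar)) / (r - 1)
    pbar = (n1s * p1 + n2s * p2) / (r * nbar)
    s2 = (n1s * (p1 - pbar) ** 2 + n2s * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1s * h1 + n2s * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0

    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    theta = np.where(valid, theta, np.nan)
    return theta


def delta_af(freq1, freq2):
    """Signed allele-frequency difference f1 - f2."""
    freq1 = np.asarray(freq1, dtype=float)
    freq2 = np.asarray(freq2, dtype=float)
    if np.any((freq1 < 0) | (freq1 > 1) | (freq2 < 0) | (freq2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return freq1 - freq2


# ---------------------------------------------------------------------------
# EHH / iHS / XP-EHH
# ---------------------------------------------------------------------------

def _refine_groups(groups: np.ndarray, column: np.ndarray) -> np.ndarray:
    """Split identity groups by one more marker column.

    A missing allele never matches anything (not even another missing
    allele), so rows with missing alleles become permanent singletons.
    """
    col = column.astype(np.int64).copy()
    miss = column == MISSING
    if miss.any():
        # unique per-row codes so missing-carrying rows match nothing
        col[miss] = 2 + np.flatnonzero(miss)
    keys = groups.astype(np.int64) * (len(column) + 2) + col
    _, new = np.unique(keys, return_inverse=True)
    return new


def _group_homozygosity(groups: np.ndarray, total_pairs: float) -> float:
    sizes = np.bincount(groups)
    return float((sizes * (sizes - 1) / 2.0).sum() / total_pairs)


def ehh(hapset: HaplotypeSet, core_index: int, core_allele: int) -> np.ndarray:
    """EHH of the core-allele carriers at every marker of the region.

    EHH at marker m is the probability that two random distinct carrier
    haplotypes are identical over every marker between the core and m
    inclusive (the core column itself is excluded: carriers share it by
    construction). EHH at the core is 1 by definition. Returns NaN
    everywhere if fewer than two carriers exist.
    """
    carriers = hapset.alleles[:, core_index] == core_allele
    n = int(carriers.sum())
    out = np.full(hapset.n_sites, np.nan)
    if n < 2:
        return out
    hap = hapset.alleles[carriers]
    total_pairs = n * (n - 1) / 2.0
    out[core_index] = 1.0
    groups = np.zeros(n, dtype=np.int64)
    for m in range(core_index + 1, hapset.n_sites):
        groups = _refine_groups(groups, hap[:, m])
        out[m] = _group_homozygosity(groups, total_pairs)
    groups = np.zeros(n, dtype=np.int64)
    for m in range(core_index - 1, -1, -1):
        groups = _refine_groups(groups, hap[:, m])
        out[m] = _group_homozygosity(groups, total_pairs)
    return out


def _ihh_one_side(ehh_vals, positions, order, cutoff):
    """Trapezoid integral of EHH in bp along ``order`` until EHH < cutoff.

    Returns (ihh, truncated): ``truncated`` is True when EHH never fell
    below the cutoff before the region edge (integral clipped by the edge).
    """
    area = 0.0
    prev_e = 1.0
    prev_p = positions[order[0]]
    for idx in order[1:]:
        e = ehh_vals[idx]
        p = positions[idx]
        if np.isnan(e):
            return area, True
        area += 0.5 * (prev_e + e) * abs(p - prev_p)
        if e < cutoff:
            return area, False
        prev_e, prev_p = e, p
    return area, True


def integrated_ehh(hapset: HaplotypeSet, core_index: int, core_allele: int,
                   cutoff: float = EHH_CUTOFF):
    """iHH: EHH integrated outward in both directions from the core.

    Returns (ihh, truncated_flag). The integral runs marker-to-marker in
    base pairs (trapezoid rule) and stops at the first marker where EHH
    drops below ``cutoff``; that crossing segment is included.
    """
    e = ehh(hapset, core_index, core_allele)
    if np.isnan(e[core_index]):
        return np.nan, True
    right = list(range(core_index, hapset.n_sites))
    left = list(range(core_index, -1, -1))
    a_r, t_r = _ihh_one_side(e, hapset.positions, right, cutoff)
    a_l, t_l = _ihh_one_side(e, hapset.positions, left, cutoff)
    return a_r + a_l, (t_r or t_l)


def ihs_unstandardized(hapset: HaplotypeSet, core_index: int,
                       cutoff: float = EHH_CUTOFF):
    """ln(iHH_ancestral / iHH_derived) at a polarized core site.

    Returns (score, truncated). NaN score when either carrier class has
    fewer than 2 haplotypes or either integral is zero.
    """
    ihh_anc, t_a = integrated_ehh(hapset, core_index, 0, cutoff)
    ihh_der, t_d = integrated_ehh(hapset, core_index, 1, cutoff)
    if not np.isfinite(ihh_anc) or not np.isfinite(ihh_der) or ihh_anc <= 0 or ihh_der <= 0:
        return np.nan, True
    return float(np.log(ihh_anc / ihh_der)), (t_a or t_d)


def _frequency_bins(freqs, width=IHS_BIN_WIDTH, min_per_bin=IHS_BIN_MIN):
    """Assign scores to frequency bins, merging sparse adjacent bins."""
    edges = np.arange(0.0, 1.0 + width, width)
    raw = np.clip(np.digitize(freqs, edges) - 1, 0, len(edges) - 2)
    # merge bins with < min_per_bin scores into their left neighbour
    labels = sorted(set(raw.tolist()))
    remap = {}
    merged = []  # list of lists of raw labels
    for lab in labels:
        if merged and sum((raw == x).sum() for x in merged[-1]) < min_per_bin:
            merged[-1].append(lab)
        else:
            merged.append([lab])
    # a trailing sparse group merges backwards
    if len(merged) > 1 and sum((raw == x).sum() for x in merged[-1]) < min_per_bin:
        merged[-2].extend(merged.pop())
    for gi, group in enumerate(merged):
        for lab in group:
            remap[lab] = gi
    return np.asarray([remap[x] for x in raw])


def standardize_scores(scores, freqs, width=IHS_BIN_WIDTH, min_per_bin=IHS_BIN_MIN):
    """Standardize scores to mean 0 / sd 1 within frequency bins.

    NaN scores stay NaN and do not enter the bin moments. Bins with fewer
    than ``min_per_bin`` usable scores are merged with neighbours; a bin
    with zero variance yields NaN standardized scores.
    """
    scores = np.asarray(scores, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out = np.full_like(scores, np.nan)
    ok = np.isfinite(scores) & np.isfinite(freqs)
    if not ok.any():
        return out
    bins = _frequency_bins(freqs[ok], width, min_per_bin)
    vals = scores[ok]
    std = np.full_like(vals, np.nan)
    for b in np.unique(bins):
        sel = bins == b
        mu = vals[sel].mean()
        sd = vals[sel].std(ddof=0)
        if sd > 0:
            std[sel] = (vals[sel] - mu) / sd
        elif sel.sum() == 1:
            std[sel] = 0.0
    out[ok] = std
    return out


def ihs_scan(hapset: HaplotypeSet, maf_floor: float = MAF_FLOOR,
             cutoff: float = EHH_CUTOFF, exclude_truncated: bool = True):
    """Standardized iHS for every eligible site of one population.

    Sites failing the MAF floor, unpolarized sites, and (by default)
    sites whose integral was clipped by the region edge get NaN.

    Returns (standardized, unstandardized, truncated_flags).
    """
    freqs = hapset.derived_freq()
    maf = np.minimum(freqs, 1 - freqs)
    raw = np.full(hapset.n_sites, np.nan)
    trunc = np.zeros(hapset.n_sites, dtype=bool)
    for j in range(hapset.n_sites):
        if not hapset.polarized[j] or not np.isfinite(maf[j]) or maf[j] <= maf_floor:
            continue
        raw[j], trunc[j] = ihs_unstandardized(hapset, j, cutoff)
    usable = raw.copy()
    if exclude_truncated:
        usable[trunc] = np.nan
    std = standardize_scores(usable, freqs)
    return std, raw, trunc


def xpehh_unstandardized(hap1: HaplotypeSet, hap2: HaplotypeSet, core_index: int,
                         cutoff: float = EHH_CUTOFF):
    """ln(iHH_pop1 / iHH_pop2) over all haplotypes of each population.

    EHH here is computed over the whole population (both alleles pooled,
    i.e. core allele unconditional), the usual cross-population contrast.
    Positive values mean longer haplotypes (stronger sweep) in pop1.
    """
    e1, t1 = _pooled_ihh(hap1, core_index, cutoff)
    e2, t2 = _pooled_ihh(hap2, core_index, cutoff)
    if not np.isfinite(e1) or not np.isfinite(e2) or e1 <= 0 or e2 <= 0:
        return np.nan, True
    return float(np.log(e1 / e2)), (t1 or t2)


def _pooled_ihh(hapset: HaplotypeSet, core_index: int, cutoff: float):
    """iHH of the whole sample at a site (identity over all haplotypes).

    The core column is neutralized so every haplotype counts as a carrier;
    identity comparisons never include the core column itself.
    """
    if hapset.n_haplotypes < 2:
        return np.nan, True
    alleles = hapset.alleles.copy()
    alleles[:, core_index] = 0
    pooled = HaplotypeSet(alleles, hapset.positions, hapset.chromosome,
                          hapset.populations, hapset.samples, hapset.polarized)
    return integrated_ehh(pooled, core_index, 0, cutoff)


def xpehh_scan(hap1: HaplotypeSet, hap2: HaplotypeSet, maf_floor: float = MAF_FLOOR,
               cutoff: float = EHH_CUTOFF, exclude_truncated: bool = True):
    """Genome-wide standardized XP-EHH (pop1 vs reference pop2)."""
    f1 = hap1.derived_freq()
    f2 = hap2.derived_freq()
    with np.errstate(invalid="ignore"):
        pooled = (f1 * hap1.n_haplotypes + f2 * hap2.n_haplotypes) / (
            hap1.n_haplotypes + hap2.n_haplotypes
        )
    maf = np.minimum(pooled, 1 - pooled)
    raw = np.full(hap1.n_sites, np.nan)
    trunc = np.zeros(hap1.n_sites, dtype=bool)
    for j in range(hap1.n_sites):
        if not np.isfinite(maf[j]) or maf[j] <= maf_floor:
            continue
        raw[j], trunc[j] = xpehh_unstandardized(hap1, hap2, j, cutoff)
    usable = raw.copy()
    if exclude_truncated:
        usable[trunc] = np.nan
    ok = np.isfinite(usable)
    std = np.full_like(raw, np.nan)
    if ok.sum() >= 2 and usable[ok].std(ddof=0) > 0:
        std[ok] = (usable[ok] - usable[ok].mean()) / usable[ok].std(ddof=0)
    return std, raw, trunc


# ---------------------------------------------------------------------------
# LD and diversity
# ---------------------------------------------------------------------------

def ld_r2(matrix: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of allele indicators or dosages.

    ``matrix`` is haplotype x site (0/1/-1) or individual x site dosage
    with NaN for missing. Returns NaN when either variant is monomorphic
    over complete observations.
    """
    x = np.asarray(matrix[:, i], dtype=float)
    y = np.asarray(matrix[:, j], dtype=float)
    x[x == MISSING] = np.nan
    y[y == MISSING] = np.nan
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def mean_pairwise_diff(hapset: HaplotypeSet, site_mask=None) -> float:
    """pi-bar: average pairwise count of differing sites, all distinct pairs.

    pi_bar = 2 * sum_{i<j} pi_ij / (n * (n-1)). Missing alleles never count
    as differences. Raises for fewer than two haplotypes.
    """
    alleles = hapset.alleles if site_mask is None else hapset.alleles[:, site_mask]
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("pi-bar requires at least two haplotypes")
    total = 0.0
    for i in range(n - 1):
        a = alleles[i]
        rest = alleles[i + 1 :]
        both = (a != MISSING) & (rest != MISSING)
        total += ((a != rest) & both).sum()
    return 2.0 * total / (n * (n - 1))
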