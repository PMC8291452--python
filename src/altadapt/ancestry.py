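"""Archaic local-ancestry calling from donor copy-probability tensors.

Chromosome painting against a donor panel (a Denisovan, a Neanderthal,
the Ust'-Ishim early-modern genome, a Han Chinese and a Yoruba genome)
yields, over many replicate runs, the probability that each recipient
haplotype copies from each donor at each site. Per (haplotype, site) the
runs supporting each donor (copy probability > 0.8) are counted and a
thresholded voting rule assigns one of six labels:

* a modern donor (Han-like / Ust'-Ishim-like / African-like) when that
  donor holds the overall maximum count and exceeds the quorum;
* an archaic donor (Denisovan-like / Neanderthal-like, larger count wins)
  when its count exceeds the quorum while the African (YRI) count stays
  at or below a small ceiling and the combined modern count at or below
  the quorum — the African ceiling vetoes calls explainable by deep
  shared ancestry;
* Uncertain otherwise.

With the published panel (1 Denisovan x 1 Neanderthal x 1 Ust'-Ishim x
39 Han x 108 YRI = 4,212 runs) the quorum is 421 runs (10%) and the YRI
ceiling 42 runs (1%); both scale with the run count R as floor(0.10*R)
and floor(0.01*R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROB_CUTOFF = 0.8
MODERN_QUORUM_FRACTION = 0.10
YRI_CEILING_FRACTION = 0.01

ARCHAIC_DONORS = ("Denisovan", "Neanderthal")
MODERN_DONORS = ("Ust'-Ishim", "Han", "YRI")
DONOR_LABELS = {
    "Denisovan": "Denisovan-like",
    "Neanderthal": "Neanderthal-like",
    "Ust'-Ishim": "Ust'-Ishim-like",
    "Han": "Han-like",
    "YRI": "African-like",
}
UNCERTAIN = "Uncertain"
ANCESTRY_CATEGORIES = tuple(DONOR_LABELS.values()) + (UNCERTAIN,)


@dataclass
class CopyProbabilityTensor:
    """Donor copy probabilities P indexed (run, donor, haplotype, site).

    Probabilities sum to 1 over donors at every (run, haplotype, site).
    """

    P: np.ndarray
    donors: tuple
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 4:
            raise ValueError("P must be (run, donor, haplotype, site)")
        if self.P.shape[1] != len(self.donors):
            raise ValueError("donor axis length must match donor labels")
        if self.P.shape[0] < 1:
            raise ValueError("need at least one painting run")
        sums = self.P.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("copy probabilities must sum to 1 over donors")
        if self.positions is None:
            self.positions = np.arange(self.P.shape[3], dtype=np.int64)

    @property
    def n_runs(self) -> int:
        return self.P.shape[0]


@dataclass
class AncestryCall:
    """Per-(haplotype, site) ancestry labels with supporting run counts."""

    labels: np.ndarray          # (haplotype, site) of category strings
    support: np.ndarray         # (donor, haplotype, site) run counts
    donors: tuple
    positions: np.ndarray


def painting_run_count(panel_sizes: dict) -> int:
    """Number of painting replications: product of donor panel sizes.

    One individual per reference population enters each run, so the runs
    enumerate every combination of panel members.
    """
    total = 1
    for name, size in panel_sizes.items():
        if size < 1:
            raise ValueError(f"panel {name!r} must have at least one genome")
        total *= size
    return total


def call_allele_ancestry(tensor: CopyProbabilityTensor,
                         prob_cutoff: float = PROB_CUTOFF,
                         modern_quorum: int | None = None,
                         yri_ceiling: int | None = None) -> AncestryCall:
    """Apply the thresholded voting rule per (haplotype, site)."""
    R = tensor.n_runs
    if modern_quorum is None:
        modern_quorum = math.floor(MODERN_QUORUM_FRACTION * R)
    if yri_ceiling is None:
        yri_ceiling = math.floor(YRI_CEILING_FRACTION * R)
    if modern_quorum > R or yri_ceiling > R:
        raise ValueError("thresholds exceed the number of runs")

    support = (tensor.P > prob_cutoff).sum(axis=0)  # (donor, hap, site)
    donors = tensor.donors
    idx = {d: donors.index(d) for d in donors}
    arch_idx = [idx[d] for d in ARCHAIC_DONORS if d in idx]
    mod_idx = [idx[d] for d in MODERN_DONORS if d in idx]
    yri_idx = idx.get("YRI")

    n_hap, n_site = support.shape[1], support.shape[2]
    labels = np.full((n_hap, n_site), UNCERTAIN, dtype=object)

    max_all = support.max(axis=0)
    modern_counts = support[mod_idx]
    combined_modern = modern_counts.sum(axis=0)
    yri_count = support[yri_idx] if yri_idx is not None else np.zeros((n_hap, n_site))

    # modern call: donor holds the overall maximum and exceeds the quorum
    best_mod = np.argmax(modern_counts, axis=0)
    best_mod_count = np.take_along_axis(modern_counts, best_mod[None], axis=0)[0]
    modern_ok = (best_mod_count == max_all) & (best_mod_count > modern_quorum)

    # archaic call: archaic quorum + YRI ceiling + combined-modern ceiling
    arch_counts = support[arch_idx]
    best_arch = np.argmax(arch_counts, axis=0)
    best_arch_count = np.take_along_axis(arch_counts, best_arch[None], axis=0)[0]
    archaic_ok = (
        (best_arch_count > modern_quorum)
        & (yri_count <= yri_ceiling)
        & (combined_modern <= modern_quorum)
        & ~modern_ok
    )

    for j, di in enumerate(mod_idx):
        sel = modern_ok & (best_mod == j)
        labels[sel] = DONOR_LABELS[donors[di]]
    for j, di in enumerate(arch_idx):
        sel = archaic_ok & (best_arch == j)
        labels[sel] = DONOR_LABELS[donors[di]]

    return AncestryCall(labels=labels, support=support, donors=donors,
                        positions=tensor.positions)


def segments_from_calls(call: AncestryCall) -> pd.DataFrame:
    """Merge per-site calls into maximal same-label bp segments.

    Segments are half-open [start, end) where a segment containing sites
    at positions p_i..p_j spans [p_i, p_j + 1). Single-site labels are
    kept as 1-bp segments.
    """
    positions = np.asarray(call.positions)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    rows = []
    for k in range(call.labels.shape[0]):
        lab = call.labels[k]
        start = 0
        for j in range(1, len(lab) + 1):
            if j == len(lab) or lab[j] != lab[start]:
                rows.append((k, int(positions[start]), int(positions[j - 1]) + 1,
                             lab[start], j - start))
                start = j
    return pd.DataFrame(rows, columns=["haplotype", "start", "end", "label", "n_sites"])


def ancestry_fractions(call: AncestryCall) -> pd.Series:
    """Fraction of (haplotype, site) calls per ancestry category."""
    flat = pd.Series(call.labels.ravel())
    return flat.value_counts(normalize=True).reindex(
        ANCESTRY_CATEGORIES, fill_value=0.0
    )
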