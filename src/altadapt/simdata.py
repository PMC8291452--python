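"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes, with known ground truth:

* two populations (a highland focal population and a lowland reference)
  that split a few hundred generations ago, with one focal sweep locus
  whose frequency follows the deterministic log10-odds trajectory
  odds(p_g) = odds(p_0) * 10**(s*g) — exactly invertible by the
  selection-coefficient estimator — with optional binomial drift;
* optional archaic-derived haplotype blocks implanted as divergent
  shared segments in a configurable carrier fraction;
* additive phenotypes with sex and principal-component covariates;
* cis-regulated expression with batch offsets;
* donor copy-probability tensors emulating replicated chromosome
  painting against a five-donor panel.

Neutral variation comes from a standard coalescent backend (msprime) or
from a built-in two-population Wright-Fisher forward model; both sit
behind ``simulate_split_populations``. All randomness flows from the
explicit seed in the configuration; there is no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import CopyProbabilityTensor, DONOR_LABELS
from .popgen import HaplotypeSet

log = logging.getLogger(__name__)

POP1 = "TIB"  # focal highland population
POP2 = "HAN"  # lowland reference population

MUTATION_RATE = 1.25e-8          # per site per generation
GENERATION_YEARS = 25.0
SPLIT_GENERATIONS = 480          # middle of the 360-600 generation window
EFFECTIVE_SIZE = 3000
LABEL_TO_DONOR = {v: k for k, v in DONOR_LABELS.items()}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-population scenario."""

    n_hap_pop1: int = 80
    n_hap_pop2: int = 80
    n_sites: int = 150
    region_length_bp: int = 200_000
    split_generations: int = SPLIT_GENERATIONS
    selection_coefficient: float = 0.0042   # carries p0=0.03 to ~0.76 in 480 gen
    focal_index: int = 75
    focal_p0: float = 0.03
    mutation_rate: float = MUTATION_RATE
    recombination_rate: float = 1e-8
    effective_size: int = EFFECTIVE_SIZE
    generation_years: float = GENERATION_YEARS
    archaic_block: tuple | None = None   # (start_bp, end_bp, carrier_fraction)
    archaic_divergence: float = 0.3      # extra-mutation density in the block
    sweep_share_bp: int = 30_000         # swept-haplotype homogenized span
    drift: bool = False                  # binomial drift on the focal trajectory
    max_drift_retries: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_hap_pop1", "n_hap_pop2", "n_sites", "region_length_bp",
                     "split_generations", "effective_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.focal_index < self.n_sites:
            raise ValueError("focal_index must be a valid site index")
        if not 0 < self.focal_p0 < 1:
            raise ValueError("focal_p0 must lie strictly in (0, 1)")
        if self.archaic_block is not None:
            start, end, frac = self.archaic_block
            if not 0 <= frac <= 1:
                raise ValueError("carrier fraction must lie in [0, 1]")
            if not 0 <= start < end <= self.region_length_bp:
                raise ValueError("archaic block must lie inside the region")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    true_s: float
    true_tmrca_generations: float
    true_p0: float
    true_pt: float
    focal_index: int
    true_ancestry_painting: np.ndarray | None = None  # pop1 hap x site labels
    true_effect_sizes: dict = field(default_factory=dict)  # trait -> [(variant, beta)]


def sweep_trajectory(p0: float, s: float, generations: int,
                     drift_2n: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Allele-frequency path under the deterministic log10-odds sweep.

    odds(p_g) = odds(p_0) * 10**(s*g); with ``drift_2n`` set, each
    generation's deterministic update is followed by binomial resampling
    of 2N alleles.
    """
    p = np.empty(generations + 1)
    p[0] = p0
    for g in range(1, generations + 1):
        odds = p[g - 1] / (1 - p[g - 1]) * 10.0**s
        det = odds / (1 + odds)
        if drift_2n is not None:
            det = rng.binomial(drift_2n, det) / drift_2n
            if det in (0.0, 1.0):
                p[g:] = det
                return p
        p[g] = det
    return p


def _neutral_msprime(config: SimulationConfig):
    """Two-population split coalescent via msprime; returns (matrix, positions)."""
    import msprime

    demography = msprime.Demography()
    demography.add_population(name="pop1", initial_size=config.effective_size)
    demography.add_population(name="pop2", initial_size=config.effective_size)
    demography.add_population(name="anc", initial_size=config.effective_size)
    demography.add_population_split(time=config.split_generations,
                                    derived=["pop1", "pop2"], ancestral="anc")
    if config.n_hap_pop1 % 2 or config.n_hap_pop2 % 2:
        raise ValueError("haplotype counts must be even (diploid samples)")
    ts = msprime.sim_ancestry(
        samples={"pop1": config.n_hap_pop1 // 2, "pop2": config.n_hap_pop2 // 2},
        demography=demography,
        sequence_length=config.region_length_bp,
        recombination_rate=config.recombination_rate,
        ploidy=2,
        random_seed=config.seed % (2**31 - 1) + 1,
    )
    ts = msprime.sim_mutations(ts, rate=config.mutation_rate,
                               random_seed=config.seed % (2**31 - 1) + 2,
                               model=msprime.BinaryMutationModel())
    mat = ts.genotype_matrix().T.astype(np.int8)  # hap x site
    positions = np.asarray([s.position for s in ts.sites()])
    pos_int = np.unique(np.floor(positions).astype(np.int64))
    if len(pos_int) != len(positions):  # collisions after integer cast
        keep = np.concatenate([[True], np.diff(np.floor(positions)) > 0])
        mat = mat[:, keep]
        positions = positions[keep]
    mat = np.clip(mat, 0, 1)
    return mat, np.floor(positions).astype(np.int64)


def _neutral_wright_fisher(config: SimulationConfig, rng: np.random.Generator):
    """Built-in forward model: shared ancestral frequency, independent drift.

    Per site: ancestral frequency ~ Uniform(0.05, 0.95); each daughter
    population drifts by binomial resampling of 2Ne alleles for
    ``split_generations`` generations; haplotype alleles are Bernoulli
    draws at the final frequencies.
    """
    n_sites = config.n_sites
    two_n = 2 * config.effective_size
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    freqs = {}
    for pop in ("pop1", "pop2"):
        p = p_anc.copy()
        for _ in range(config.split_generations):
            p = rng.binomial(two_n, p) / two_n
        freqs[pop] = p
    h1 = (rng.random((config.n_hap_pop1, n_sites)) < freqs["pop1"]).astype(np.int8)
    h2 = (rng.random((config.n_hap_pop2, n_sites)) < freqs["pop2"]).astype(np.int8)
    mat = np.vstack([h1, h2])
    positions = np.sort(rng.choice(config.region_length_bp, size=n_sites,
                                   replace=False)).astype(np.int64)
    return mat, positions


def simulate_split_populations(config: SimulationConfig, backend: str = "msprime"):
    """Synthetic two-population haplotypes with one focal sweep locus.

    Returns ``(HaplotypeSet, TruthRecord)``. The focal site is implanted
    at ``config.focal_index``: its derived frequency in the lowland
    population stays at ``focal_p0`` while the highland frequency follows
    the deterministic sweep trajectory for ``split_generations``
    generations (binomial drift optional). Sweep carriers share a copied
    haplotype background over ``sweep_share_bp`` around the focal site,
    emulating hitchhiking. If the allele is lost or fixed under drift the
    simulation retries up to ``max_drift_retries`` times.
    """
    rng = np.random.default_rng(config.seed)
    if backend == "msprime":
        mat, positions = _neutral_msprime(config)
    elif backend == "wf":
        mat, positions = _neutral_wright_fisher(config, rng)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    # thin or keep neutral sites to n_sites - 1, then implant the focal site
    target = config.n_sites - 1
    if mat.shape[1] > target:
        keep = np.sort(rng.choice(mat.shape[1], size=target, replace=False))
        mat, positions = mat[:, keep], positions[keep]
    n1 = config.n_hap_pop1

    # focal trajectory (retry under drift if lost/fixed)
    pt = None
    for attempt in range(config.max_drift_retries):
        path = sweep_trajectory(
            config.focal_p0, config.selection_coefficient, config.split_generations,
            drift_2n=2 * config.effective_size if config.drift else None, rng=rng)
        if 0 < path[-1] < 1:
            pt = float(path[-1])
            break
    if pt is None:
        raise RuntimeError(
            f"focal allele lost or fixed under drift in all "
            f"{config.max_drift_retries} attempts; lower s or disable drift")

    fi = min(config.focal_index, mat.shape[1])
    if fi == 0:
        focal_pos = max(positions[0] - 1, 0) if len(positions) else 0
    elif fi >= len(positions):
        focal_pos = positions[-1] + 1
    else:
        focal_pos = (positions[fi - 1] + positions[fi]) // 2
        if focal_pos in (positions[fi - 1], positions[fi]):
            focal_pos = positions[fi - 1] + 1
    n_der1 = int(round(pt * n1))
    n_der2 = int(round(config.focal_p0 * config.n_hap_pop2))
    focal_col = np.zeros(mat.shape[0], dtype=np.int8)
    carriers1 = rng.choice(n1, size=n_der1, replace=False)
    carriers2 = n1 + rng.choice(config.n_hap_pop2, size=n_der2, replace=False)
    focal_col[carriers1] = 1
    focal_col[carriers2] = 1
    mat = np.insert(mat, fi, focal_col, axis=1)
    positions = np.insert(positions, fi, focal_pos)

    # hitchhiking: highland carriers copy a founder haplotype near the focal site
    if n_der1 >= 2 and config.sweep_share_bp > 0:
        half = config.sweep_share_bp // 2
        span = (positions >= focal_pos - half) & (positions <= focal_pos + half)
        founder = carriers1[0]
        mat[np.ix_(carriers1, np.flatnonzero(span))] = mat[founder, span]

    # archaic block: divergent founder segment shared by a carrier subset
    painting = np.full((n1, mat.shape[1]), "Han-like", dtype=object)
    if config.archaic_block is not None:
        start, end, frac = config.archaic_block
        in_block = (positions >= start) & (positions < end)
        n_carrier = int(round(frac * n1))
        if n_carrier and in_block.any():
            arch_carriers = rng.choice(n1, size=n_carrier, replace=False)
            founder_seg = (rng.random(int(in_block.sum()))
                           < config.archaic_divergence).astype(np.int8)
            mat[np.ix_(arch_carriers, np.flatnonzero(in_block))] = founder_seg
            painting[np.ix_(arch_carriers, np.flatnonzero(in_block))] = "Denisovan-like"

    # guarantee strictly increasing positions (insertions can tie)
    for j in range(1, len(positions)):
        if positions[j] <= positions[j - 1]:
            positions[j] = positions[j - 1] + 1

    populations = np.array([POP1] * n1 + [POP2] * config.n_hap_pop2)
    hapset = HaplotypeSet(alleles=mat, positions=positions, chromosome="1",
                          populations=populations)
    truth = TruthRecord(
        true_s=config.selection_coefficient,
        true_tmrca_generations=float(config.split_generations),
        true_p0=config.focal_p0, true_pt=pt,
        focal_index=fi, true_ancestry_painting=painting,
    )
    return hapset, truth


# ---------------------------------------------------------------------------
# Phenotypes, expression, annotations
# ---------------------------------------------------------------------------

def simulate_phenotypes(dosages: pd.DataFrame, effects: dict, noise_sd: float,
                        seed: int, covariate_scale: float = 0.5):
    """Additive phenotypes with sex and five PC covariates.

    trait = alpha + sum beta*dosage + gamma*sex + sum delta*PC + eps,
    eps ~ N(0, noise_sd^2). ``effects`` maps trait name to a list of
    (variant, beta); every referenced variant must exist in ``dosages``
    (individuals x variants). Returns (traits frame, covariates frame).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for trait, pairs in effects.items():
        for vid, _ in pairs:
            if vid not in dosages.columns:
                raise ValueError(f"effect variant {vid!r} for {trait!r} "
                                 "not in the genotype table")
    rng = np.random.default_rng(seed)
    n = len(dosages)
    cov = pd.DataFrame({"sex": rng.integers(0, 2, size=n).astype(float)},
                       index=dosages.index)
    for k in range(1, 6):
        cov[f"PC{k}"] = rng.normal(0, 1, size=n)
    traits = {}
    for trait, pairs in effects.items():
        gamma = rng.normal(0, covariate_scale)
        delta = rng.normal(0, covariate_scale, size=5)
        y = rng.normal(0, 1) + gamma * cov["sex"].to_numpy()
        y = y + cov[[f"PC{k}" for k in range(1, 6)]].to_numpy() @ delta
        for vid, beta in pairs:
            y = y + beta * dosages[vid].to_numpy(dtype=float)
        y = y + rng.normal(0, noise_sd, size=n)
        traits[trait] = y
    return pd.DataFrame(traits, index=dosages.index), cov


def simulate_expression(dosages: pd.DataFrame, eqtl_effects: dict,
                        batch_labels, noise_sd: float, seed: int,
                        batch_sd: float = 1.0):
    """Expression with cis genetic effects and additive batch offsets.

    ``eqtl_effects`` maps gene to (variant, beta) or None for genes with
    no genetic effect. Returns a samples x genes frame.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    batch_labels = np.asarray(batch_labels)
    offsets = {b: rng.normal(0, batch_sd) for b in pd.unique(batch_labels)}
    n = len(dosages)
    out = {}
    for gene, effect in eqtl_effects.items():
        y = rng.normal(0, 1) + np.array([offsets[b] for b in batch_labels])
        if effect is not None:
            vid, beta = effect
            if vid not in dosages.columns:
                raise ValueError(f"eQTL variant {vid!r} not in the genotype table")
            y = y + beta * dosages[vid].to_numpy(dtype=float)
        y = y + rng.normal(0, noise_sd, size=n)
        out[gene] = y
    return pd.DataFrame(out, index=dosages.index)


def simulate_annotations(hapset: HaplotypeSet, truth: TruthRecord, seed: int,
                         gene_span_bp: int = 20_000,
                         focal_consequence: str = "missense_variant",
                         focal_cadd: float = 25.0) -> pd.DataFrame:
    """VEP-style annotation table; the focal sweep variant gets an
    injected protein-changing consequence and a high CADD score.

    Genes tile the region every ``gene_span_bp``; most variants are
    benign (intronic/intergenic, low CADD/GERP), a few carry eQTL flags.
    """
    rng = np.random.default_rng(seed)
    n = hapset.n_sites
    benign = ["intron_variant", "intergenic_variant", "synonymous_variant",
              "upstream_gene_variant", "downstream_gene_variant"]
    rows = []
    for j in range(n):
        vid = f"var{j}"
        gene = f"gene{int(hapset.positions[j]) // gene_span_bp}"
        if j == truth.focal_index:
            rows.append((vid, int(hapset.positions[j]), focal_consequence,
                         focal_cadd, 4.0, "", gene))
        else:
            cons = benign[rng.integers(0, len(benign))]
            cadd = float(np.clip(rng.gamma(2.0, 2.0), 0, 14.9))
            gerp = float(np.clip(rng.normal(-0.5, 1.0), -12, 1.9))
            eqtl = f"{gene}:placenta" if rng.random() < 0.05 else ""
            rows.append((vid, int(hapset.positions[j]), cons, cadd, gerp,
                         eqtl, gene))
    return pd.DataFrame(rows, columns=["variant_id", "position", "consequence",
                                       "cadd", "gerp", "eqtl", "gene"])


# ---------------------------------------------------------------------------
# Copy-probability tensors
# ---------------------------------------------------------------------------

def simulate_copy_probabilities(painting: np.ndarray, n_runs: int,
                                concentration: float, seed: int,
                                support: float = 0.8,
                                noiseless: bool = False,
                                donors: tuple = tuple(DONOR_LABELS)) -> CopyProbabilityTensor:
    """Copy-probability tensor consistent with a truth painting.

    Per (run, haplotype, site): with probability ``support`` the true
    donor's probability is drawn above 0.8 (the callers' cutoff) and the
    remainder is split over the other donors by a Dirichlet draw; else
    all donor probabilities come from a symmetric Dirichlet with the
    given ``concentration``. ``noiseless`` gives the true donor
    probability exactly 1 in every run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not 0 <= support <= 1:
        raise ValueError("support must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_hap, n_site = painting.shape
    n_don = len(donors)
    donor_index = {d: i for i, d in enumerate(donors)}
    true_idx = np.vectorize(
        lambda lab: donor_index[LABEL_TO_DONOR.get(lab, lab)])(painting)

    P = np.empty((n_runs, n_don, n_hap, n_site))
    for k in range(n_hap):
        for l in range(n_site):
            t = true_idx[k, l]
            if noiseless:
                block = np.zeros((n_runs, n_don))
                block[:, t] = 1.0
            else:
                supported = rng.random(n_runs) < support
                block = rng.dirichlet(np.full(n_don, concentration), size=n_runs)
                n_sup = int(supported.sum())
                if n_sup:
                    top = rng.uniform(0.8 + 1e-9, 1.0, size=n_sup)
                    rest = rng.dirichlet(np.full(n_don - 1, concentration),
                                         size=n_sup) * (1 - top)[:, None]
                    sup_block = np.empty((n_sup, n_don))
                    others = [d for d in range(n_don) if d != t]
                    sup_block[:, t] = top
                    sup_block[:, others] = rest
                    block[supported] = sup_block
            P[:, :, k, l] = block
    return CopyProbabilityTensor(P=P, donors=tuple(donors))


def uniform_copy_probabilities(n_runs: int, n_hap: int, n_site: int,
                               donors: tuple = tuple(DONOR_LABELS)) -> CopyProbabilityTensor:
    """Maximally ambiguous tensor: every donor equally likely in every run."""
    n_don = len(donors)
    P = np.full((n_runs, n_don, n_hap, n_site), 1.0 / n_don)
    return CopyProbabilityTensor(P=P, donors=tuple(donors))
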