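"""Phenotype association, cis-eQTL scan, epistasis models and enrichment.

All genotype-phenotype models are ordinary least squares under the
additive coding (dosage 0/1/2), with sex and the leading five principal
components as covariates; expression models use a batch covariate instead.
Multiple testing is controlled per family (all variant x trait pairs; all
variant x gene cis pairs) by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 100_000
FDR_ALPHA = 0.05


@dataclass
class RegressionFit:
    """One OLS fit: intercept, per-predictor effects, fit diagnostics."""
    alpha: float
    beta: dict
    se: dict
    pvalues: dict
    resid_var: float
    r_squared: float
    n: int


@dataclass
class EnrichmentResult:
    """2x2 enrichment of a gene category among candidates."""
    a1: int
    a2: int
    n1: int
    n2: int
    odds_ratio: float
    p: float
    p_adjusted: float | None = None


def _ols(y: np.ndarray, X: pd.DataFrame) -> RegressionFit:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"), missing="drop")
    res = model.fit()
    params = res.params
    return RegressionFit(
        alpha=float(params["const"]),
        beta={k: float(v) for k, v in params.items() if k != "const"},
        se={k: float(v) for k, v in res.bse.items() if k != "const"},
        pvalues={k: float(v) for k, v in res.pvalues.items() if k != "const"},
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        r_squared=float(res.rsquared),
        n=int(res.nobs),
    )


def additive_assoc(dosage, trait, covariates: pd.DataFrame) -> RegressionFit | None:
    """Additive-model OLS of one trait on one variant's dosage + covariates.

    Returns None (logged) for constant dosage or too few complete rows
    (fewer than n_covariates + 3).
    """
    X = covariates.copy()
    X.insert(0, "dosage", np.asarray(dosage, dtype=float))
    y = np.asarray(trait, dtype=float)
    complete = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    if complete.sum() < covariates.shape[1] + 3:
        log.warning("too few complete observations (%d); association skipped",
                    int(complete.sum()))
        return None
    if np.nanstd(X.loc[complete, "dosage"]) == 0:
        log.warning("constant dosage; association skipped")
        return None
    return _ols(y[complete], X.loc[complete])


def assoc_scan(dosages: pd.DataFrame, traits: pd.DataFrame,
               covariates: pd.DataFrame, alpha: float = FDR_ALPHA) -> pd.DataFrame:
    """All variant x trait additive associations with one BH-FDR family.

    ``dosages``: individuals x variants; ``traits``: individuals x traits.
    Returns a long frame (variant, trait, beta, se, p, p_adjusted,
    significant); the family size is n_variants x n_traits.
    """
    rows = []
    for vid in dosages.columns:
        for tname in traits.columns:
            fit = additive_assoc(dosages[vid], traits[tname], covariates)
            if fit is None:
                rows.append((vid, tname, np.nan, np.nan, np.nan))
            else:
                rows.append((vid, tname, fit.beta["dosage"], fit.se["dosage"],
                             fit.pvalues["dosage"]))
    df = pd.DataFrame(rows, columns=["variant", "trait", "beta", "se", "p"])
    df["p_adjusted"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        clipped = np.maximum(df.loc[ok, "p"].to_numpy(), np.nextafter(0, 1))
        df.loc[ok, "p_adjusted"] = bh_fdr(clipped)
    df["significant"] = df["p_adjusted"] < alpha
    return df


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def eqtl_scan(dosages: pd.DataFrame, expression: pd.DataFrame,
              batch: pd.Series, variant_pos: dict, gene_pos: dict,
              cis_window: int = CIS_WINDOW_BP, alpha: float = FDR_ALPHA) -> pd.DataFrame:
    """cis-eQTL scan: expression ~ dosage + batch within the cis window.

    A variant-gene pair is tested only when their positions are within
    ``cis_window`` bp. BH-FDR runs over all tested pairs; significant
    pairs are flagged cis-associated. Genes without expression variance
    are skipped with a warning.
    """
    batch_cov = pd.get_dummies(pd.Series(batch), drop_first=True, dtype=float)
    batch_cov.index = expression.index
    rows = []
    for gene in expression.columns:
        expr = expression[gene].to_numpy(dtype=float)
        if np.nanstd(expr) == 0:
            log.warning("gene %r has zero expression variance; skipped", gene)
            continue
        gpos = gene_pos[gene]
        for vid in dosages.columns:
            if abs(variant_pos[vid] - gpos) > cis_window:
                continue
            fit = additive_assoc(dosages[vid], expr, batch_cov)
            if fit is None:
                continue
            rows.append((vid, gene, fit.beta["dosage"], fit.pvalues["dosage"]))
    df = pd.DataFrame(rows, columns=["variant", "gene", "beta", "p"])
    if len(df):
        df["p_adjusted"] = bh_fdr(np.maximum(df["p"].to_numpy(),
                                             np.nextafter(0, 1)))
        df["cis_associated"] = df["p_adjusted"] < alpha
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
        df["cis_associated"] = pd.Series(dtype=bool)
    return df


def eqtl_hypothesis_count(n_variants: int, n_genes: int) -> int:
    """Size of the eQTL testing family (variants x genes)."""
    if n_variants < 0 or n_genes < 0:
        raise ValueError("counts must be non-negative")
    return n_variants * n_genes


@dataclass
class EpistasisResult:
    """Fits of the nested single / additive / interaction models."""
    model1: dict            # per-variant single-predictor fits
    model2: RegressionFit   # both variants, additive
    model3: RegressionFit   # + interaction term
    p_1_vs_2: dict          # per single model: F-test p against model 2
    p_2_vs_3: float
    identifiable: bool = True


def epistasis_models(trait, dosage1, dosage2, covariates: pd.DataFrame) -> EpistasisResult:
    """Nested-model comparison for two variants on one trait.

    Model 1: y ~ x_i; Model 2: y ~ x1 + x2; Model 3 adds x1*x2. ANOVA
    F-tests compare Model 1 vs 2 (necessity of each variant) and Model 2
    vs 3 (interaction). Perfectly collinear dosages (r^2 = 1) make
    Models 2/3 unidentifiable.
    """
    y = np.asarray(trait, dtype=float)
    x1 = np.asarray(dosage1, dtype=float)
    x2 = np.asarray(dosage2, dtype=float)
    if np.std(x1) == 0 or np.std(x2) == 0:
        raise ValueError("both dosages must vary")
    r = np.corrcoef(x1, x2)[0, 1]
    identifiable = bool(r * r < 1 - 1e-12)

    def frame(**cols):
        X = covariates.copy()
        for i, (k, v) in enumerate(cols.items()):
            X.insert(i, k, v)
        return X

    m1 = {"x1": _ols(y, frame(x1=x1)), "x2": _ols(y, frame(x2=x2))}
    if not identifiable:
        return EpistasisResult(m1, None, None, {}, np.nan, identifiable=False)
    m2 = _ols(y, frame(x1=x1, x2=x2))
    m3 = _ols(y, frame(x1=x1, x2=x2, x1x2=x1 * x2))

    def f_test(small: RegressionFit, big: RegressionFit, df_diff: int) -> float:
        n = big.n
        k_big = len(big.beta) + 1
        rss_small = small.resid_var * (n - len(small.beta) - 1)
        rss_big = big.resid_var * (n - k_big)
        df_big = n - k_big
        if df_big <= 0 or rss_big <= 0:
            return np.nan
        f = ((rss_small - rss_big) / df_diff) / (rss_big / df_big)
        return float(scipy.stats.f.sf(f, df_diff, df_big))

    p12 = {k: f_test(m1[k], m2, 1) for k in m1}
    p23 = f_test(m2, m3, 1)
    return EpistasisResult(m1, m2, m3, p12, p23, identifiable=True)


def cross_conditional_assoc(dosages: pd.DataFrame, trait, covariates: pd.DataFrame,
                            loci: list) -> pd.DataFrame:
    """Each associated locus re-tested with every other locus as covariate."""
    rows = []
    for target, conditioning in itertools.permutations(loci, 2):
        cov = covariates.copy()
        cov["conditioned_on"] = dosages[conditioning].to_numpy(dtype=float)
        fit = additive_assoc(dosages[target], trait, cov)
        if fit is not None:
            rows.append((target, conditioning, fit.beta["dosage"],
                         fit.pvalues["dosage"]))
    return pd.DataFrame(rows, columns=["variant", "conditioned_on", "beta", "p"])


def enrichment_or(a1: int, a2: int, n1: int, n2: int) -> EnrichmentResult:
    """Odds ratio (A1/A2)/(N1/N2) with one-sided Fisher's exact p.

    A1/A2: candidate genes inside/outside the category; N1/N2: genome
    genes inside/outside. The Fisher table is [[A1, A2], [N1-A1, N2-A2]]
    (candidates vs rest of the genome), tested for enrichment (greater).
    """
    for v in (a1, a2, n1, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a2 == 0 or n1 == 0:
        odds = float("inf")
    else:
        odds = (a1 / a2) / (n1 / n2)
    table = [[a1, a2], [n1 - a1, n2 - a2]]
    _, p = scipy.stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(a1, a2, n1, n2, odds, float(p))


def enrich_categories(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-adjust Fisher p-values across tested categories."""
    adj = bh_fdr([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def tissue_specific(expression: pd.DataFrame, tissue_labels: pd.Series) -> pd.DataFrame:
    """Tissue-specificity calls per gene across tissue sample groups.

    A gene is specific to tissue T when (a) its median in T is at least
    twice its median in every other tissue and (b) its lower quartile in
    T is strictly above the highest upper quartile among other tissues.
    ``expression``: samples x genes; ``tissue_labels``: per-sample tissue.
    """
    tissues = pd.unique(tissue_labels)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    groups = {t: expression[np.asarray(tissue_labels) == t] for t in tissues}
    for t, g in groups.items():
        if len(g) < 4:
            raise ValueError(f"tissue {t!r} has fewer than 4 samples")
    rows = []
    for gene in expression.columns:
        med = {t: float(np.median(g[gene])) for t, g in groups.items()}
        q1 = {t: float(np.percentile(g[gene], 25)) for t, g in groups.items()}
        q3 = {t: float(np.percentile(g[gene], 75)) for t, g in groups.items()}
        call = None
        for t in tissues:
            others = [u for u in tissues if u != t]
            if med[t] == 0:
                continue
            if all(med[t] >= 2 * med[u] for u in others) and q1[t] > max(
                q3[u] for u in others
            ):
                call = t
                break
        rows.append((gene, call))
    return pd.DataFrame(rows, columns=["gene", "specific_tissue"])


def af_altitude_correlation(dosages_or_haps: pd.DataFrame, group_labels,
                            group_altitudes: dict):
    """Per-group adaptive-allele frequency and its Pearson r with altitude.

    ``dosages_or_haps``: per-sample allele counts for one variant (dosage
    0/1/2, NaN missing) indexed like ``group_labels``; ``group_altitudes``
    maps group label to metres. Groups with zero genotyped alleles are
    dropped (logged). Returns (per-group frequency frame, r, p); r is NaN
    when the frequency is constant.
    """
    labels = np.asarray(group_labels)
    dos = np.asarray(dosages_or_haps, dtype=float)
    rows = []
    for g in pd.unique(labels):
        d = dos[labels == g]
        d = d[np.isfinite(d)]
        if d.size == 0:
            log.warning("group %r has no genotyped alleles; dropped", g)
            continue
        rows.append((g, group_altitudes[g], d.sum() / (2 * d.size), 2 * d.size))
    df = pd.DataFrame(rows, columns=["group", "altitude", "freq", "n_alleles"])
    if len(df) < 3:
        raise ValueError("need at least three groups with data")
    if df["freq"].std() == 0 or df["altitude"].std() == 0:
        return df, float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(df["freq"], df["altitude"])
    return df, float(r), float(p)
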