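"""Association models, FDR, eQTL scan, epistasis, enrichment, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from altadapt.assoc import (additive_assoc, af_altitude_correlation, bh_fdr,
                            enrichment_or, epistasis_models,
                            eqtl_hypothesis_count, eqtl_scan, tissue_specific)


def _covariates(rng, n):
    cov = pd.DataFrame({"sex": rng.integers(0, 2, size=n).astype(float)})
    for k in range(1, 6):
        cov[f"PC{k}"] = rng.normal(size=n)
    return cov


class TestAdditiveAssoc:
    def test_noiseless_recovery(self, rng):
        n = 40
        cov = _covariates(rng, n)
        dosage = rng.integers(0, 3, size=n).astype(float)
        y = 3.0 + 2.0 * dosage
        fit = additive_assoc(dosage, y, cov)
        assert fit.beta["dosage"] == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.alpha == pytest.approx(3.0, abs=1e-8)

    def test_constant_dosage_skipped(self, rng):
        cov = _covariates(rng, 30)
        assert additive_assoc(np.ones(30), rng.normal(size=30), cov) is None

    def test_matches_normal_equations_oracle(self, rng):
        # 12-row fixture solved via the closed-form normal equations
        n = 12
        x = rng.integers(0, 3, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = rng.normal(size=n)
        cov = pd.DataFrame({"sex": sex})
        X = np.column_stack([np.ones(n), x, sex])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        fit = additive_assoc(x, y, cov)
        assert fit.alpha == pytest.approx(beta_hat[0], abs=1e-10)
        assert fit.beta["dosage"] == pytest.approx(beta_hat[1], abs=1e-10)
        assert fit.beta["sex"] == pytest.approx(beta_hat[2], abs=1e-10)

    def test_covariate_shift_invariance(self, rng):
        n = 50
        cov = _covariates(rng, n)
        dosage = rng.integers(0, 3, size=n).astype(float)
        y = rng.normal(size=n) + dosage
        a = additive_assoc(dosage, y, cov)
        b = additive_assoc(dosage, y, cov + 7.0)
        assert a.beta["dosage"] == pytest.approx(b.beta["dosage"], abs=1e-10)

    def test_null_p_uniform(self, rng):
        n = 60
        cov = _covariates(rng, n)
        ps = []
        for _ in range(300):
            dosage = rng.integers(0, 3, size=n).astype(float)
            if dosage.std() == 0:
                continue
            y = rng.normal(size=n)
            ps.append(additive_assoc(dosage, y, cov).pvalues["dosage"])
        stat, p = scipy.stats.kstest(ps, "uniform")
        assert p > 0.01


def bh_bruteforce(p):
    """Step-up definition: min over j >= i of p(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBHFDR:
    def test_analytic_examples(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_fdr([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9])

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bh_bruteforce(p), atol=1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestEqtlScan:
    def _setup(self, rng, n=40):
        dosages = pd.DataFrame({
            "v_near": rng.integers(0, 3, size=n).astype(float),
            "v_far": rng.integers(0, 3, size=n).astype(float),
        })
        batch = pd.Series(["b1"] * (n // 2) + ["b2"] * (n - n // 2))
        vpos = {"v_near": 50_000, "v_far": 400_000}
        gpos = {"geneA": 100_000}
        return dosages, batch, vpos, gpos

    def test_window_rule_excludes_distant_pair(self, rng):
        dosages, batch, vpos, gpos = self._setup(rng)
        expr = pd.DataFrame({"geneA": rng.normal(size=len(dosages))})
        res = eqtl_scan(dosages, expr, batch, vpos, gpos)
        assert set(res["variant"]) == {"v_near"}

    def test_injected_effect_recovered(self, rng):
        dosages, batch, vpos, gpos = self._setup(rng)
        expr = pd.DataFrame({
            "geneA": 1.0 + 2.5 * dosages["v_near"]
            + np.where(batch == "b2", 0.7, 0.0)})
        res = eqtl_scan(dosages, expr, batch, vpos, gpos)
        hit = res[res["variant"] == "v_near"].iloc[0]
        assert hit["beta"] == pytest.approx(2.5, abs=1e-8)
        assert hit["cis_associated"]

    def test_hypothesis_family_size(self):
        assert eqtl_hypothesis_count(592, 310) == 183_520


class TestEpistasis:
    def test_noiseless_additive(self, rng):
        n = 60
        cov = _covariates(rng, n)
        x1 = rng.integers(0, 3, size=n).astype(float)
        x2 = rng.integers(0, 3, size=n).astype(float)
        y = 1.0 + 0.5 * x1 - 1.2 * x2
        res = epistasis_models(y, x1, x2, cov)
        assert res.model2.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.model2.beta["x1"] == pytest.approx(0.5, abs=1e-8)
        assert res.model2.beta["x2"] == pytest.approx(-1.2, abs=1e-8)

    def test_r_squared_nested_monotone(self, rng):
        n = 80
        cov = _covariates(rng, n)
        x1 = rng.integers(0, 3, size=n).astype(float)
        x2 = rng.integers(0, 3, size=n).astype(float)
        y = 0.3 * x1 + rng.normal(size=n)
        res = epistasis_models(y, x1, x2, cov)
        assert res.model1["x1"].r_squared <= res.model2.r_squared + 1e-12
        assert res.model2.r_squared <= res.model3.r_squared + 1e-12

    def test_interaction_coefficient_recovered(self, rng):
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 120
            cov = _covariates(rng, n)
            x1 = rng.integers(0, 3, size=n).astype(float)
            x2 = rng.integers(0, 3, size=n).astype(float)
            beta3 = 0.8
            y = 0.5 * x1 + 0.5 * x2 + beta3 * x1 * x2 + rng.normal(size=n)
            res = epistasis_models(y, x1, x2, cov)
            est = res.model3.beta["x1x2"]
            se = res.model3.se["x1x2"]
            hits += abs(est - beta3) <= 2 * se
        assert hits >= 0.9 * n_rep

    def test_collinear_dosages_unidentifiable(self, rng):
        n = 30
        cov = _covariates(rng, n)
        x = rng.integers(0, 3, size=n).astype(float)
        res = epistasis_models(rng.normal(size=n), x, 2 * x, cov)
        assert not res.identifiable


class TestEnrichment:
    def test_odds_ratio_arithmetic(self):
        res = enrichment_or(4, 96, 10, 890)
        assert res.odds_ratio == pytest.approx((4 / 96) / (10 / 890))
        assert res.odds_ratio == pytest.approx(3.708, abs=5e-3)

    def test_proportional_table_gives_one(self):
        res = enrichment_or(5, 95, 50, 950)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_fisher_p_equals_hypergeometric_tail(self):
        a1, a2, n1, n2 = 6, 14, 40, 160
        res = enrichment_or(a1, a2, n1, n2)
        # P(X >= a1) for X ~ Hypergeom(total, row1 total, col1 total)
        total = a1 + a2 + (n1 - a1) + (n2 - a2)
        want = scipy.stats.hypergeom.sf(a1 - 1, total, a1 + a2, n1)
        assert res.p == pytest.approx(want, rel=1e-9)

    def test_reciprocal_under_row_swap(self):
        a = enrichment_or(4, 96, 10, 890)
        b = enrichment_or(96, 4, 890, 10)
        assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)


class TestTissueSpecific:
    def _expr(self, values_by_tissue):
        rows, labels = [], []
        for t, vals in values_by_tissue.items():
            for v in vals:
                rows.append(v)
                labels.append(t)
        return pd.DataFrame({"g": rows}), pd.Series(labels)

    def test_specific_when_both_conditions_hold(self):
        expr, labels = self._expr({
            "placenta": [8, 9, 11, 12],     # median 10, Q1 8.75
            "liver": [3, 4, 4, 5],          # median 4, Q3 4.25
            "lung": [2, 3, 3, 4],
        })
        res = tissue_specific(expr, labels)
        assert res.iloc[0]["specific_tissue"] == "placenta"

    def test_median_ratio_fails(self):
        expr, labels = self._expr({
            "placenta": [9, 10, 10, 11],
            "liver": [5, 6, 6, 7],          # 10 < 2 * 6
            "lung": [2, 3, 3, 4],
        })
        assert tissue_specific(expr, labels).iloc[0]["specific_tissue"] is None

    def test_quartile_overlap_fails(self):
        expr, labels = self._expr({
            "placenta": [2, 3, 17, 18],     # median 10 but Q1 = 2.75
            "liver": [3, 4, 4, 5],
            "lung": [2, 3, 3, 4],
        })
        assert tissue_specific(expr, labels).iloc[0]["specific_tissue"] is None

    def test_all_zero_not_specific(self):
        expr, labels = self._expr({
            "placenta": [0, 0, 0, 0],
            "liver": [0, 0, 0, 0],
        })
        assert tissue_specific(expr, labels).iloc[0]["specific_tissue"] is None


class TestAltitudeCorrelation:
    def test_linear_frequencies_give_r_one(self):
        groups = np.repeat(["a", "b", "c", "d"], 10)
        alts = {"a": 3000.0, "b": 3500.0, "c": 4000.0, "d": 4500.0}
        # dosage means rising linearly with altitude
        dosage = np.concatenate([np.full(10, 0.2), np.full(10, 0.6),
                                 np.full(10, 1.0), np.full(10, 1.4)])
        df, r, p = af_altitude_correlation(dosage, groups, alts)
        assert r == pytest.approx(1.0)

    def test_constant_frequency_undefined(self):
        groups = np.repeat(["a", "b", "c"], 4)
        alts = {"a": 3000.0, "b": 3500.0, "c": 4000.0}
        df, r, p = af_altitude_correlation(np.ones(12), groups, alts)
        assert np.isnan(r)

    def test_matches_closed_form_pearson(self, rng):
        # seven regional groups, like the published sampling design
        labels = np.repeat([f"g{i}" for i in range(7)], 6)
        alts = {f"g{i}": 3000.0 + 250 * i for i in range(7)}
        dosage = rng.integers(0, 3, size=42).astype(float)
        df, r, p = af_altitude_correlation(dosage, labels, alts)
        x, y = df["freq"].to_numpy(), df["altitude"].to_numpy()
        want = (((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(want, abs=1e-12)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            af_altitude_correlation(np.ones(8), np.repeat(["a", "b"], 4),
                                    {"a": 1.0, "b": 2.0})
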