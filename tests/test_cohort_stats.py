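import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coronaflow.cohort_stats import (
    classify_displacement_pattern,
    classify_max_slab,
    fit_lmm,
    paired_t,
    phenotype_association,
    rpd_group_comparison,
    shapiro_wilk,
)
from coronaflow.synthetic import CohortSpec, simulate_cohort


def _table_from_means(per_eye_means, flags=None):
    """Build a cohort table from {eye: {slab: mean}}."""
    rows = []
    for eye, means in per_eye_means.items():
        f = (flags or {}).get(eye, {})
        for slab, val in means.items():
            rows.append({
                "patient_id": eye, "eye_id": eye, "slab": slab, "roi": "whole",
                "displacement_um": val,
                "rpd": f.get("rpd", False), "dped": f.get("dped", False),
                "drusen": f.get("drusen", False), "irora": f.get("irora", False),
            })
    return pd.DataFrame(rows)


class TestShapiroWilk:
    def test_exact_normal_scores(self):
        n = 20
        q = stats.norm.ppf((np.arange(1, n + 1) - 3 / 8) / (n + 1 / 4))
        w, p = shapiro_wilk(q)
        assert w > 0.99

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0] * 10)

    def test_bimodal_rejected_as_normal(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-5, 0.3, 25), rng.normal(5, 0.3, 25)])
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestPairedT:
    def test_identical_samples(self):
        r = paired_t([1, 2, 3], [1, 2, 3])
        assert r.mean_diff == 0.0
        assert r.p == 1.0
        assert r.degenerate

    def test_constant_shift_degenerate(self):
        r = paired_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.mean_diff == 1.0
        assert r.degenerate
        assert np.isnan(r.p)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x0 = rng.normal(10, 2, 18)
        x1 = x0 + rng.normal(1, 1, 18)
        r = paired_t(x0, x1)
        t_ref, p_ref = stats.ttest_rel(x1, x0)
        assert r.t == pytest.approx(t_ref)
        assert r.p == pytest.approx(p_ref)
        d = (x1 - x0).mean() / (x1 - x0).std(ddof=1)
        assert r.cohens_d == pytest.approx(d)

    def test_swap_negates(self):
        rng = np.random.default_rng(2)
        x0 = rng.normal(size=15)
        x1 = rng.normal(size=15)
        a = paired_t(x0, x1)
        b = paired_t(x1, x0)
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_power_monte_carlo(self):
        # diff ~ N(1, 1), n=18, alpha=0.01: empirical power matches the
        # exact noncentral-t power (0.8929) within 3 binomial SDs
        n = 18
        tc = stats.t.ppf(1 - 0.005, n - 1)
        ncp = np.sqrt(n)
        power = 1 - stats.nct.cdf(tc, n - 1, ncp) + stats.nct.cdf(-tc, n - 1, ncp)
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x0 = rng.normal(10, 2, n)
            x1 = x0 + rng.normal(1, 1, n)
            if paired_t(x0, x1).p < 0.01:
                hits += 1
        assert abs(hits - 200 * power) <= 3 * np.sqrt(200 * power * (1 - power))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1, 2], [1, 2, 3])


class TestFitLMM:
    def test_zero_noise_exact(self):
        spec = CohortSpec(5, {"SCP": 13.0, "DCP": 15.0, "CC": 19.0})
        r = fit_lmm(simulate_cohort(spec, seed=0))
        assert r.boundary
        assert r.estimates == {"SCP": 13.0, "DCP": 15.0, "CC": 19.0}

    def test_balanced_emm_equals_raw_means(self):
        spec = CohortSpec(12, {"SCP": 13.0, "DCP": 15.0, "CC": 19.0}, 5.0, 3.0)
        tab = simulate_cohort(spec, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fit_lmm(tab)
        raw = tab.groupby("slab")["displacement_um"].mean()
        for slab in ("SCP", "DCP", "CC"):
            assert r.estimates[slab] == pytest.approx(raw[slab], abs=1e-8)

    def test_ci_brackets_estimate(self):
        spec = CohortSpec(18, {"SCP": 13.0, "DCP": 15.0, "CC": 19.0}, 5.0, 3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fit_lmm(simulate_cohort(spec, seed=5))
        for s in r.estimates:
            assert r.ci_low[s] < r.estimates[s] < r.ci_high[s]
        assert r.patient_var >= 0 and r.residual_var >= 0

    def test_variance_components_recovered_n50(self):
        spec = CohortSpec(50, {"SCP": 13.0, "DCP": 15.0, "CC": 19.0}, 5.0, 3.0)
        pv, rv = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(20):
                r = fit_lmm(simulate_cohort(spec, seed=seed))
                pv.append(r.patient_var)
                rv.append(r.residual_var)
        assert np.mean(pv) == pytest.approx(25.0, rel=0.3)
        assert np.mean(rv) == pytest.approx(9.0, rel=0.3)

    def test_contrast_pvalues_present(self):
        spec = CohortSpec(18, {"SCP": 13.0, "DCP": 15.0, "CC": 19.0}, 5.0, 3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fit_lmm(simulate_cohort(spec, seed=8))
        assert set(r.contrast_p) == {"SCP", "DCP"}
        assert r.omnibus_p is not None and 0 <= r.omnibus_p <= 1

    def test_too_few_patients_rejected(self):
        tab = _table_from_means({"E1": {"SCP": 10, "DCP": 11, "CC": 12}})
        with pytest.raises(ValueError):
            fit_lmm(tab)


class TestClassifyMaxSlab:
    def test_simple_argmax(self):
        tab = _table_from_means({"E1": {"SCP": 10.0, "DCP": 20.0, "CC": 15.0}})
        out = classify_max_slab(tab)
        assert out.loc[0, "max_slab"] == "DCP"
        assert not out.loc[0, "tie"]

    def test_tie_goes_to_cc(self):
        tab = _table_from_means({"E1": {"SCP": 10.0, "DCP": 20.0, "CC": 20.0}})
        out = classify_max_slab(tab)
        assert out.loc[0, "max_slab"] == "CC"
        assert out.loc[0, "tie"]

    def test_missing_slab_skipped_with_warning(self):
        tab = _table_from_means({"E1": {"SCP": 10.0, "DCP": 20.0}})
        with pytest.warns(UserWarning, match="missing slab"):
            out = classify_max_slab(tab)
        assert out.empty

    def test_simulation_selects_dcp(self):
        # DCP exceeds the others by 3x the residual SD
        spec = CohortSpec(40, {"SCP": 10.0, "DCP": 19.0, "CC": 10.0},
                          patient_sd_um=2.0, residual_sd_um=3.0)
        out = classify_max_slab(simulate_cohort(spec, seed=4))
        assert (out.max_slab == "DCP").mean() > 0.9


class TestClassifyPattern:
    def test_mild_when_dcp_cc_close(self):
        tab = _table_from_means({
            "E1": {"SCP": 5.0, "DCP": 8.0, "CC": 9.0},
            "E2": {"SCP": 5.0, "DCP": 25.0, "CC": 10.0},
            "E3": {"SCP": 5.0, "DCP": 10.0, "CC": 25.0},
        })
        out = classify_displacement_pattern(tab).set_index("eye_id")["pattern"]
        assert out["E1"] == "mild"
        assert out["E2"] == "DCP-max"
        assert out["E3"] == "CC-max"


class TestPhenotypeAssociation:
    def test_six_of_nine(self):
        labels = {f"E{i}": ("DCP" if i < 9 else "CC") for i in range(12)}
        flags = {f"E{i}": i < 6 for i in range(12)}
        r = phenotype_association(labels, flags, "DCP")
        assert r.n_stratum == 9 and r.n_positive == 6
        assert r.proportion_pct == 66.7

    def test_all_of_three(self):
        labels = {f"E{i}": ("CC" if i < 3 else "DCP") for i in range(10)}
        flags = {f"E{i}": i < 3 for i in range(10)}
        r = phenotype_association(labels, flags, "CC")
        assert r.proportion_pct == 100.0

    def test_zero_of_n(self):
        labels = {f"E{i}": "DCP" for i in range(5)}
        flags = {f"E{i}": False for i in range(5)}
        r = phenotype_association(labels, flags, "DCP")
        assert r.proportion_pct == 0.0

    def test_empty_stratum_reported_as_none(self):
        labels = {"E0": "DCP"}
        flags = {"E0": True}
        r = phenotype_association(labels, flags, "SCP")
        assert r.proportion_pct is None
        assert r.fisher_p is None

    def test_fisher_matches_scipy(self):
        labels = {f"E{i}": ("DCP" if i < 9 else "other") for i in range(18)}
        flags = {f"E{i}": (i < 6 or i >= 15) for i in range(18)}
        r = phenotype_association(labels, flags, "DCP")
        _, p_ref = stats.fisher_exact([[6, 3], [3, 6]], alternative="two-sided")
        assert r.fisher_p == pytest.approx(p_ref)

    def test_row_order_invariance(self):
        labels = {f"E{i}": ("DCP" if i % 2 else "CC") for i in range(10)}
        flags = {f"E{i}": i in (1, 3, 4) for i in range(10)}
        a = phenotype_association(labels, flags, "DCP")
        rev_l = dict(reversed(list(labels.items())))
        rev_f = dict(reversed(list(flags.items())))
        b = phenotype_association(rev_l, rev_f, "DCP")
        assert a.proportion_pct == b.proportion_pct
        assert a.fisher_p == b.fisher_p

    def test_strata_sum(self):
        labels = {f"E{i}": ("DCP" if i < 9 else "CC") for i in range(18)}
        flags = {f"E{i}": i % 3 == 0 for i in range(18)}
        a = phenotype_association(labels, flags, "DCP")
        b = phenotype_association(labels, flags, "CC")
        assert a.n_positive + b.n_positive == sum(flags.values())


class TestRPDComparison:
    def test_detects_group_difference(self):
        spec = CohortSpec(
            40, {"DCP": 12.0, "SCP": 10.0, "CC": 11.0},
            residual_sd_um=1.0,
            phenotype_rates={"rpd": 0.5},
            phenotype_effects_um={("rpd", "DCP"): 8.0},
        )
        tab = simulate_cohort(spec, seed=6)
        t, p = rpd_group_comparison(tab, "DCP")
        assert p < 0.01 and t > 0
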