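"""Cohort-level statistics on per-eye/per-slab displacement records.

Normality screening, paired comparisons with effect sizes, a random-intercept
linear mixed model across vascular slabs (CC as the reference category,
estimated marginal means with 95% CI), per-eye classification by the slab of
greatest displacement, and phenotype cross-tabulation with exact tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SLABS

__all__ = [
    "PairedTResult",
    "LMMResult",
    "AssociationResult",
    "shapiro_wilk",
    "paired_t",
    "fit_lmm",
    "classify_max_slab",
    "classify_displacement_pattern",
    "phenotype_association",
    "rpd_group_comparison",
]

#: tie-break priority when two slabs share the per-eye maximum
TIE_ORDER = ("CC", "DCP", "SCP")


def shapiro_wilk(sample) -> Tuple[float, float]:
    """Shapiro-Wilk normality test; returns ``(W, p)``."""
    x = np.asarray(sample, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairedTResult:
    mean_diff: float
    ci95: Tuple[float, float]
    t: float
    p: float
    cohens_d: float
    n: int
    degenerate: bool = False


def paired_t(x0, x1) -> PairedTResult:
    """Paired t-test of ``x1 - x0`` with 95% CI and Cohen's d.

    Cohen's d is ``mean(diff) / sd(diff)``.  Zero-variance differences are
    flagged degenerate: p = 1 when the paired samples are identical, NaN for
    a nonzero constant shift.
    """
    a = np.asarray(x0, dtype=np.float64)
    b = np.asarray(x1, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    diff = b - a
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if md == 0.0 else float("nan")
        return PairedTResult(md, (md, md), float("nan"), p, float("nan"), n, degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    tval = md / se
    p = 2.0 * stats.t.sf(abs(tval), n - 1)
    return PairedTResult(md, (md - tcrit * se, md + tcrit * se), float(tval), float(p), md / sd, n)


@dataclass
class LMMResult:
    """Random-intercept mixed model of displacement by slab.

    ``estimates`` are the estimated marginal means per slab with normal-
    approximation 95% CIs; contrasts are tested against the CC reference.
    """

    estimates: Dict[str, float]
    se: Dict[str, float]
    ci_low: Dict[str, float]
    ci_high: Dict[str, float]
    patient_var: float
    residual_var: float
    contrast_p: Dict[str, float]
    omnibus_p: Optional[float] = None
    boundary: bool = False
    reference: str = "CC"
    notes: List[str] = field(default_factory=list)


def _eye_slab_means(table: pd.DataFrame, response_roi: str) -> pd.DataFrame:
    df = table[table["roi"] == response_roi] if "roi" in table.columns else table
    if df.empty:
        raise ValueError(f"no rows for roi {response_roi!r}")
    return df


def fit_lmm(table: pd.DataFrame, response_roi: str = "whole", reference: str = "CC") -> LMMResult:
    """Fit displacement ~ slab with a per-patient random intercept (REML).

    Returns estimated marginal means per slab with 95% CI, the variance
    components, Wald p-values for the non-reference slabs versus the
    reference, and a likelihood-ratio omnibus p for the slab factor.
    Degenerate inputs (zero residual variance) return the raw cell means
    with a boundary flag instead of raising.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _eye_slab_means(table, response_roi).copy()
    slabs = [s for s in SLABS if s in set(df["slab"])]
    if reference not in slabs:
        raise ValueError(f"reference slab {reference!r} absent from table")
    if df.groupby("patient_id")["slab"].nunique().max() < 2 or df["patient_id"].nunique() < 2:
        raise ValueError("need >= 2 patients with >= 2 slabs each")

    cell_means = df.groupby("slab")["displacement_um"].mean()
    within = df.groupby(["patient_id", "slab"])["displacement_um"].transform("mean")
    total_resid = float(((df["displacement_um"] - df.groupby("slab")["displacement_um"].transform("mean")) ** 2).sum())
    if total_resid < 1e-14:
        # zero-noise cohort: the model is singular, report the exact means
        est = {s: float(cell_means[s]) for s in slabs}
        return LMMResult(
            estimates=est,
            se={s: 0.0 for s in slabs},
            ci_low=dict(est),
            ci_high=dict(est),
            patient_var=0.0,
            residual_var=0.0,
            contrast_p={s: float("nan") for s in slabs if s != reference},
            omnibus_p=None,
            boundary=True,
            reference=reference,
            notes=["zero residual variance; exact cell means returned"],
        )

    formula = f"displacement_um ~ C(slab, Treatment('{reference}'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["patient_id"])
        fit = model.fit(reml=True)

        # omnibus slab effect via ML likelihood-ratio test
        omnibus_p: Optional[float] = None
        try:
            full_ml = smf.mixedlm(formula, df, groups=df["patient_id"]).fit(reml=False)
            null_ml = smf.mixedlm("displacement_um ~ 1", df, groups=df["patient_id"]).fit(reml=False)
            lr = 2.0 * (full_ml.llf - null_ml.llf)
            omnibus_p = float(stats.chi2.sf(max(lr, 0.0), df=len(slabs) - 1))
        except Exception:
            pass

    params = fit.fe_params
    cov = fit.cov_params().iloc[: len(params), : len(params)]
    names = list(params.index)
    # between-patient df for EMM intervals (balanced random-intercept design);
    # the normal approximation undercovers at n ~ 18
    df_eff = max(df["patient_id"].nunique() - 1, 1)
    z = stats.t.ppf(0.975, df_eff)

    estimates, se_d, lo, hi, pvals = {}, {}, {}, {}, {}
    for slab in slabs:
        contrast = np.zeros(len(names))
        contrast[names.index("Intercept")] = 1.0
        term = f"C(slab, Treatment('{reference}'))[T.{slab}]"
        if term in names:
            contrast[names.index(term)] = 1.0
        est = float(contrast @ params.values)
        se = float(np.sqrt(contrast @ cov.values @ contrast))
        estimates[slab] = est
        se_d[slab] = se
        lo[slab] = est - z * se
        hi[slab] = est + z * se
        if slab != reference:
            pvals[slab] = float(fit.pvalues[term]) if term in fit.pvalues.index else float("nan")

    re_var = float(fit.cov_re.iloc[0, 0])
    boundary = re_var < 1e-10
    return LMMResult(
        estimates=estimates,
        se=se_d,
        ci_low=lo,
        ci_high=hi,
        patient_var=re_var,
        residual_var=float(fit.scale),
        contrast_p=pvals,
        omnibus_p=omnibus_p,
        boundary=boundary,
        reference=reference,
    )


def classify_max_slab(table: pd.DataFrame, response_roi: str = "whole") -> pd.DataFrame:
    """Per-eye label of the slab with the greatest mean displacement.

    Ties are broken by the fixed priority CC > DCP > SCP and flagged.  Eyes
    missing a slab are skipped with a warning.
    """
    df = _eye_slab_means(table, response_roi)
    records = []
    for eye, sub in df.groupby("eye_id", sort=True):
        means = sub.groupby("slab")["displacement_um"].mean()
        if not all(s in means.index for s in SLABS):
            warnings.warn(f"eye {eye}: missing slab, skipped")
            continue
        winners = [s for s in TIE_ORDER if np.isclose(means[s], means.max())]
        records.append({"eye_id": eye, "max_slab": winners[0], "tie": len(winners) > 1})
    return pd.DataFrame(records, columns=["eye_id", "max_slab", "tie"])


def classify_displacement_pattern(
    table: pd.DataFrame,
    mild_margin_um: float = 2.0,
    response_roi: str = "whole",
) -> pd.DataFrame:
    """Per-eye displacement pattern stratum.

    ``mild`` when the DCP and CC means are within ``mild_margin_um`` of each
    other (similarly mild reorganization), otherwise the slab of greatest
    displacement (``DCP-max``, ``CC-max`` or ``SCP-max``).
    """
    df = _eye_slab_means(table, response_roi)
    records = []
    for eye, sub in df.groupby("eye_id", sort=True):
        means = sub.groupby("slab")["displacement_um"].mean()
        if not all(s in means.index for s in SLABS):
            warnings.warn(f"eye {eye}: missing slab, skipped")
            continue
        if abs(means["DCP"] - means["CC"]) <= mild_margin_um:
            label = "mild"
        else:
            winners = [s for s in TIE_ORDER if np.isclose(means[s], means.max())]
            label = f"{winners[0]}-max"
        records.append({"eye_id": eye, "pattern": label})
    return pd.DataFrame(records, columns=["eye_id", "pattern"])


@dataclass
class AssociationResult:
    """Cross-tabulation of one stratum against one phenotype flag."""

    stratum: str
    phenotype: str
    n_stratum: int
    n_positive: int
    proportion_pct: Optional[float]  # one decimal, None for an empty stratum
    fisher_p: Optional[float]
    table: np.ndarray  # 2x2: [in/out stratum] x [flag/no flag]


def phenotype_association(
    labels: Mapping[str, str] | pd.Series,
    phenotypes: Mapping[str, bool] | pd.Series,
    stratum: str,
) -> AssociationResult:
    """Proportion of flagged eyes within a stratum, plus Fisher's exact test.

    ``labels`` maps eye id to its stratum label; ``phenotypes`` maps eye id
    to a boolean flag.  The p-value is from the two-sided Fisher exact test
    on the 2x2 collapse (in/out of stratum x flag present/absent).
    """
    lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    ph = pd.Series(dict(phenotypes)) if not isinstance(phenotypes, pd.Series) else phenotypes
    ph = ph.reindex(lab.index)
    if ph.isna().any():
        raise ValueError("phenotype flags missing for some eyes")
    ph = ph.astype(bool)
    in_s = lab == stratum
    phenotype_name = ph.name if ph.name else "phenotype"
    a = int((in_s & ph).sum())
    b = int((in_s & ~ph).sum())
    c = int((~in_s & ph).sum())
    d = int((~in_s & ~ph).sum())
    tab = np.array([[a, b], [c, d]])
    n = a + b
    if n == 0:
        return AssociationResult(stratum, str(phenotype_name), 0, 0, None, None, tab)
    prop = round(100.0 * a / n, 1)
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return AssociationResult(stratum, str(phenotype_name), n, a, prop, float(p), tab)


def rpd_group_comparison(table: pd.DataFrame, slab: str, response_roi: str = "whole") -> Tuple[float, float]:
    """Welch two-sample t-test of per-eye slab means by RPD status.

    Returns ``(t, p)``.  The original analysis does not name its test; Welch
    is an explicit artifact choice.
    """
    df = _eye_slab_means(table, response_roi)
    df = df[df["slab"] == slab]
    means = df.groupby("eye_id").agg(y=("displacement_um", "mean"), rpd=("rpd", "first"))
    g1 = means.loc[means["rpd"].astype(bool), "y"].to_numpy()
    g0 = means.loc[~means["rpd"].astype(bool), "y"].to_numpy()
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("need >= 2 eyes per RPD group")
    res = stats.ttest_ind(g1, g0, equal_var=False)
    return float(res.statistic), float(res.pvalue)
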