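"""Inferential chain over component activations and behavior.

The chain mirrors a standard age x load x performance analysis:

1. mixed-design (repeated-measures) ANOVA on the per-component BOLD
   load effects, with component as the within-subject factor and age
   group as the between-subjects factor (Greenhouse-Geisser corrected
   p reported alongside the uncorrected one);
2. post-hoc pooled-variance two-sample t-tests per component (old vs
   young load effect) and one-sample t-tests against zero within group;
3. linear regressions of a behavioral outcome on effect-coded centered
   age, the within-group z-scored load effect, and their interaction;
4. Spearman rank correlations between activation and accuracy within
   group, compared across groups with the Fisher r-to-z statistic

       z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).

All p-values are two-sided; no multiple-testing correction is applied
by default (a Holm option exists behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

from .task import CONDITIONS


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    p_gg: float | None = None     # Greenhouse-Geisser corrected
    epsilon: float | None = None


@dataclass(frozen=True)
class TTestResult:
    label: str
    t: float
    df: int
    p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    coefficients: pd.DataFrame    # predictor, beta, t, p
    df_resid: int
    r_squared: float
    F: float
    df_model: int
    notes: str = ""


@dataclass(frozen=True)
class CorrelationComparison:
    rho1: float
    n1: int
    rho2: float
    n2: int
    z: float
    p: float


# ---------------------------------------------------------------------------

def rm_anova(load_effects: np.ndarray, groups: list[str] | np.ndarray,
             subject_ids: list[str] | None = None) -> list[AnovaResult]:
    """Mixed ANOVA: within = component, between = group.

    ``load_effects`` is subject x component, complete (no missing
    cells).  With N subjects in two groups and k components the
    interaction degrees of freedom are (k - 1, (N - 2)(k - 1)).
    """
    le = np.asarray(load_effects, dtype=float)
    if not np.isfinite(le).all():
        raise ValueError("load effects contain missing values")
    groups = np.asarray(groups)
    n, k = le.shape
    if len(groups) != n:
        raise ValueError("group labels must match subject count")
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    ids = subject_ids if subject_ids is not None else [f"s{i}" for i in range(n)]
    long = pd.DataFrame({
        "subject": np.repeat(ids, k),
        "group": np.repeat(groups, k),
        "component": np.tile([f"c{j}" for j in range(k)], n),
        "value": le.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=long, dv="value", within="component",
                             subject="subject", between="group",
                             correction=True)
    out = []
    for _, row in aov.iterrows():
        eps = row.get("eps", np.nan)
        p_gg = row.get("p_GG_corr", row.get("p-GG-corr", np.nan))
        p_unc = row.get("p_unc", row.get("p-unc"))
        out.append(AnovaResult(
            effect=str(row["Source"]),
            F=float(row["F"]),
            df_num=int(row["DF1"]),
            df_den=int(row["DF2"]),
            p=float(p_unc),
            p_gg=None if pd.isna(p_gg) else float(p_gg),
            epsilon=None if pd.isna(eps) else float(eps),
        ))
    return out


def two_sample_t(x: np.ndarray, y: np.ndarray, label: str = "") -> TTestResult:
    """Pooled-variance two-sample t-test (classic equal-variance form)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
           / (n1 + n2 - 2))
    if sp2 == 0:
        if np.isclose(x.mean(), y.mean()):
            return TTestResult(label, np.nan, n1 + n2 - 2, np.nan,
                               n1 + n2, degenerate=True)
        raise ValueError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(label, float(t), df, float(p), n1 + n2)


def one_sample_t(x: np.ndarray, label: str = "",
                 popmean: float = 0.0) -> TTestResult:
    x = np.asarray(x, float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        return TTestResult(label, np.nan, len(x) - 1, np.nan, len(x),
                           degenerate=not np.isclose(x.mean(), popmean))
    t, p = sps.ttest_1samp(x, popmean)
    return TTestResult(label, float(t), len(x) - 1, float(p), len(x))


def ttests(load_effects: np.ndarray, groups: np.ndarray,
           component_labels: list | None = None
           ) -> tuple[list[TTestResult], list[TTestResult]]:
    """Per-component post-hoc t-tests on the load effect.

    Returns (two-sample old-vs-young results, within-group one-sample
    results against zero).
    """
    le = np.asarray(load_effects, float)
    groups = np.asarray(groups)
    labels = (component_labels if component_labels is not None
              else list(range(le.shape[1])))
    gnames = list(dict.fromkeys(groups))  # stable order
    if len(gnames) != 2:
        raise ValueError("exactly two groups required")
    two, one = [], []
    for j, lab in enumerate(labels):
        a = le[groups == gnames[0], j]
        b = le[groups == gnames[1], j]
        two.append(two_sample_t(a, b, label=f"{lab}:{gnames[0]}-{gnames[1]}"))
        for gname, vals in ((gnames[0], a), (gnames[1], b)):
            one.append(one_sample_t(vals, label=f"{lab}:{gname}"))
    return two, one


# ---------------------------------------------------------------------------

def _effect_code(groups: np.ndarray, old_label: str = "old") -> np.ndarray:
    """+/-1 coding (old = +1) centered by the possibly unbalanced mean."""
    code = np.where(np.asarray(groups) == old_label, 1.0, -1.0)
    return code - code.mean()


def zscore_within_group(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """z-score a predictor separately inside each group (sample SD)."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    for g in np.unique(groups):
        m = np.asarray(groups) == g
        sd = x[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant predictor within group {g!r}")
        out[m] = (x[m] - x[m].mean()) / sd
    return out


def interaction_regression(outcome: np.ndarray, groups: np.ndarray,
                           predictor: np.ndarray, *, outcome_name: str = "y",
                           predictor_name: str = "load_effect",
                           ) -> RegressionResult:
    """OLS of outcome on {age, predictor, age x predictor} + intercept.

    Age is effect coded (+1 old / -1 young) and centered; the predictor
    is z-scored within group, making the fit invariant to affine
    rescaling of the raw predictor.  Residual df follow the usual
    n - p - 1 convention.
    """
    y = np.asarray(outcome, float)
    if not np.isfinite(y).all() or not np.isfinite(predictor).all():
        raise ValueError("outcome/predictor contain non-finite values")
    age = _effect_code(groups)
    z = zscore_within_group(predictor, groups)
    X = np.column_stack([age, z, age * z])
    names = ["age", predictor_name, f"age*{predictor_name}"]
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError("collinear regression design")
    fit = sm.OLS(y, Xc).fit()
    coef = pd.DataFrame({
        "predictor": ["intercept"] + names,
        "beta": fit.params,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    r2 = float(fit.rsquared)
    return RegressionResult(
        outcome=outcome_name, coefficients=coef.reset_index(drop=True),
        df_resid=int(fit.df_resid), r_squared=r2 if np.isfinite(r2) else 0.0,
        F=float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0,
        df_model=int(fit.df_model),
        notes="df convention: n - p - 1 residual df",
    )


def simple_regression(outcome: np.ndarray, predictor: np.ndarray, *,
                      outcome_name: str = "y",
                      predictor_name: str = "x") -> RegressionResult:
    """Single-predictor OLS (used for the within-group follow-ups)."""
    y = np.asarray(outcome, float)
    X = sm.add_constant(np.asarray(predictor, float), has_constant="add")
    fit = sm.OLS(y, X).fit()
    coef = pd.DataFrame({
        "predictor": ["intercept", predictor_name],
        "beta": fit.params, "t": fit.tvalues, "p": fit.pvalues,
    })
    r2 = float(fit.rsquared)
    return RegressionResult(
        outcome=outcome_name, coefficients=coef.reset_index(drop=True),
        df_resid=int(fit.df_resid), r_squared=r2 if np.isfinite(r2) else 0.0,
        F=float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0,
        df_model=int(fit.df_model),
    )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined rank correlation")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def compare_correlations(rho1: float, n1: int, rho2: float,
                         n2: int) -> CorrelationComparison:
    """Fisher r-to-z comparison of two independent correlations."""
    for rho, n in ((rho1, n1), (rho2, n2)):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1 for the Fisher transform")
        if n < 4:
            raise ValueError("need n >= 4 per sample")
    z1, z2 = np.arctanh(rho1), np.arctanh(rho2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2 * sps.norm.sf(abs(z))
    return CorrelationComparison(rho1, n1, rho2, n2, float(z), float(p))


# ---------------------------------------------------------------------------
# the full chain

@dataclass
class AnalysisReport:
    anova: list[AnovaResult] = field(default_factory=list)
    posthoc_two_sample: list[TTestResult] = field(default_factory=list)
    posthoc_one_sample: list[TTestResult] = field(default_factory=list)
    components_of_interest: list = field(default_factory=list)
    regressions: list[RegressionResult] = field(default_factory=list)
    correlations: pd.DataFrame | None = None
    correlation_comparisons: list[tuple[str, CorrelationComparison]] = field(
        default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["ANALYSIS REPORT", "=" * 40, "", "Mixed ANOVA (load effects)"]
        for a in self.anova:
            gg = f", p_GG={a.p_gg:.4g}" if a.p_gg is not None else ""
            lines.append(f"  {a.effect}: F({a.df_num},{a.df_den})={a.F:.3g}, "
                         f"p={a.p:.4g}{gg}")
        lines.append("")
        lines.append("Post-hoc two-sample t (load effect, per component)")
        for t in self.posthoc_two_sample:
            lines.append(f"  {t.label}: t({t.df})={t.t:.3g}, p={t.p:.4g}")
        lines.append(f"Components of interest: {self.components_of_interest}")
        lines.append("")
        for r in self.regressions:
            lines.append(f"Regression [{r.outcome}]: R2={r.r_squared:.3f}, "
                         f"F({r.df_model},{r.df_resid})={r.F:.3g}")
            for _, row in r.coefficients.iterrows():
                lines.append(f"    {row['predictor']}: b={row['beta']:.4g}, "
                             f"t={row['t']:.3g}, p={row['p']:.4g}")
        if self.correlations is not None and len(self.correlations):
            lines.append("")
            lines.append("Spearman activation-accuracy correlations")
            for _, row in self.correlations.iterrows():
                lines.append(f"  {row['label']} {row['condition']} "
                             f"{row['group']}: rho={row['rho']:.3f} "
                             f"(n={row['n']})")
        for label, c in self.correlation_comparisons:
            lines.append(f"  {label}: z={c.z:.3f}, p={c.p:.4g} "
                         f"(rho_young={c.rho1:.3f} n={c.n1}, "
                         f"rho_old={c.rho2:.3f} n={c.n2})")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def analysis_report(activation_table, behavior_summary,
                    selected: dict[str, int], *, alpha: float = 0.05,
                    holm: bool = False) -> AnalysisReport:
    """Run the full inferential chain on selected components.

    ``activation_table`` is a :class:`~nback_ica.regression.ActivationTable`
    over the selected component indices; ``behavior_summary`` a
    :class:`~nback_ica.behavior.BehaviorSummary`; ``selected`` maps
    component names to indices within the activation table's component
    axis.  Stages: mixed ANOVA -> post-hoc t-tests -> interaction
    regressions for cost outcomes on components of interest ->
    within-group per-condition regressions and Spearman correlations ->
    Fisher r-to-z group comparison.
    """
    report = AnalysisReport()
    if not selected:
        report.warnings.append("empty component selection; nothing to test")
        return report

    per_subject = behavior_summary.per_subject
    included = per_subject[per_subject["included"]].copy()
    act_ids = list(activation_table.subject_ids)
    keep = [sid for sid in act_ids if sid in set(included["subject"])]
    if not keep:
        raise ValueError("stage alignment: no overlapping subjects between "
                         "activation table and behavior summary")
    beh = included.set_index("subject").loc[keep]
    idx = [act_ids.index(sid) for sid in keep]
    groups = np.asarray([activation_table.groups[i] for i in idx])
    if not (np.asarray(beh["group"]) == groups).all():
        raise ValueError("stage alignment: group labels disagree between "
                         "activation and behavior tables")

    names = list(selected)
    cols = [list(activation_table.components).index(selected[n])
            for n in names]
    le = activation_table.load_effect[np.ix_(idx, cols)]
    act = activation_table.activation[np.ix_(idx, cols)]

    if le.shape[1] >= 2:
        report.anova = rm_anova(le, groups, subject_ids=keep)
    else:
        report.warnings.append("fewer than 2 components: ANOVA skipped")

    two, one = ttests(le, groups, component_labels=names)
    report.posthoc_two_sample = two
    report.posthoc_one_sample = one
    pvals = np.array([t.p for t in two])
    if holm:
        from statsmodels.stats.multitest import multipletests
        rej, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    else:
        rej = pvals < alpha
    coi = [names[j] for j in range(len(names)) if rej[j]]
    report.components_of_interest = coi

    corr_rows = []
    gnames = list(dict.fromkeys(groups))
    for name in coi:
        j = names.index(name)
        for outcome in ("accuracy_cost", "speed_cost"):
            report.regressions.append(interaction_regression(
                beh[outcome].to_numpy(), groups, le[:, j],
                outcome_name=f"{outcome}~{name}", predictor_name=name))
        z_act = np.column_stack([
            zscore_within_group(act[:, j, k], groups) for k in range(3)])
        for k, cond in enumerate(CONDITIONS):
            acc = beh[f"accuracy_{cond}"].to_numpy()
            for g in gnames:
                m = groups == g
                report.regressions.append(simple_regression(
                    acc[m], z_act[m, k],
                    outcome_name=f"accuracy_{cond}[{g}]~{name}",
                    predictor_name=name))
                corr_rows.append((name, cond, g,
                                  spearman(act[m, j, k], acc[m]),
                                  int(m.sum())))
            sub = [r for r in corr_rows
                   if r[0] == name and r[1] == cond]
            by_group = {r[2]: r for r in sub}
            if len(by_group) == 2:
                r1 = by_group[gnames[0]]
                r2 = by_group[gnames[1]]
                report.correlation_comparisons.append((
                    f"{name}:{cond}:{gnames[0]}-vs-{gnames[1]}",
                    compare_correlations(r1[3], r1[4], r2[3], r2[4])))
    report.correlations = pd.DataFrame(
        corr_rows, columns=["label", "condition", "group", "rho", "n"])
    return report
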