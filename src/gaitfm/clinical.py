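"""Clinical statistics: change from baseline, paired effects, stepwise
regression and power analysis.

The analysis mirrors the standard pre/post rehabilitation workflow:

* :func:`change_from_baseline` — per-outcome complete-case paired change
  (discharge − admission) with mean, SD, percent of the admission mean, a
  normality-gated paired test, and the paired Cohen's *d* (mean change /
  SD of change);
* :func:`paired_test` — Shapiro–Wilk decides between the paired *t*-test
  and the Wilcoxon signed-rank test (Lilliefors-corrected
  Kolmogorov–Smirnov is reported alongside);
* :func:`stepwise_regression` — classic forward selection with backward
  elimination on partial-F p-values (enter 0.05 / remove 0.10), reporting
  per-step R², the final unstandardized and standardized coefficients,
  variance inflation factors and residual normality;
* :func:`sample_size_paired` — smallest n for a two-tailed paired t-test
  at a given power, by noncentral-t iteration, for changes of 10/20/30%
  of the baseline mean scaled by the observed SD of change.

Complete-case pairing is per outcome (not listwise), which is why the
reported n varies across outcomes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ChangeSummary",
    "RegressionStep",
    "RegressionResult",
    "SampleSizeResult",
    "change_from_baseline",
    "paired_test",
    "cohens_d_paired",
    "stepwise_regression",
    "sample_size_paired",
    "sample_size_grid",
    "pivot_outcomes",
]

ALPHA = 0.05


def cohens_d_paired(mean_change: float, sd_change: float) -> float:
    """Paired effect size d = mean of change / SD of change."""
    if sd_change <= 0:
        raise ValueError("sd_change must be positive")
    return mean_change / sd_change


@dataclass
class ChangeSummary:
    outcome: str
    n: int
    admission_mean: float
    admission_sd: float
    discharge_mean: float
    discharge_sd: float
    mean_change: float
    sd_change: float
    percent_change: float  # |mean change| as % of admission mean
    test_used: str  # "paired-t" | "wilcoxon"
    p_value: float
    cohens_d: float
    shapiro_p: float
    ks_p: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["flags"] = ";".join(self.flags)
        return d


def paired_test(changes: np.ndarray) -> tuple[str, float]:
    """Normality-gated paired test on a vector of within-subject changes.

    Shapiro–Wilk p ≥ 0.05 → one-sample t on the changes (equivalent to the
    paired t); otherwise Wilcoxon signed-rank (exact for n ≤ 25 without
    ties, normal approximation with continuity correction above).
    """
    x = np.asarray(changes, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 paired changes")
    if np.all(x == 0):
        return "wilcoxon", 1.0
    if np.ptp(x) == 0:  # constant non-zero shift: SW undefined, t degenerate
        return "paired-t", 0.0
    sw_p = stats.shapiro(x).pvalue
    if sw_p >= ALPHA:
        return "paired-t", float(stats.ttest_1samp(x, 0.0).pvalue)
    nonzero = x[x != 0]
    ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(x, method=method, correction=(method == "approx"))
    return "wilcoxon", float(res.pvalue)


def change_from_baseline(table: pd.DataFrame) -> list[ChangeSummary]:
    """Per-outcome paired change summaries from a long outcomes table.

    ``table`` columns: ``subject_id, outcome, admission, discharge``.
    Pairing is complete-case per outcome; outcomes with fewer than two
    complete pairs are skipped with a warning.
    """
    out: list[ChangeSummary] = []
    for outcome, grp in table.groupby("outcome", sort=False):
        complete = grp.dropna(subset=["admission", "discharge"])
        if len(complete) < 2:
            warnings.warn(f"outcome {outcome!r}: fewer than 2 complete pairs, skipped",
                          stacklevel=2)
            continue
        change = (complete["discharge"] - complete["admission"]).to_numpy()
        adm = complete["admission"].to_numpy()
        dis = complete["discharge"].to_numpy()
        mean_change = float(change.mean())
        sd_change = float(change.std(ddof=1))
        flags = []
        if sd_change == 0:
            flags.append("degenerate: zero SD of change")
            d = np.nan
            sw_p = np.nan
            ks_p = np.nan
        else:
            d = cohens_d_paired(mean_change, sd_change)
            sw_p = float(stats.shapiro(change).pvalue) if len(change) >= 3 else np.nan
            ks_p = (
                float(lilliefors(change, dist="norm")[1]) if len(change) >= 4 else np.nan
            )
        try:
            test_used, p = paired_test(change)
        except ValueError:
            test_used, p = "paired-t", np.nan
            flags.append("too few pairs for testing")
        out.append(
            ChangeSummary(
                outcome=str(outcome),
                n=len(complete),
                admission_mean=float(adm.mean()),
                admission_sd=float(adm.std(ddof=1)),
                discharge_mean=float(dis.mean()),
                discharge_sd=float(dis.std(ddof=1)),
                mean_change=mean_change,
                sd_change=sd_change,
                percent_change=abs(mean_change / adm.mean()) * 100.0 if adm.mean() else np.nan,
                test_used=test_used,
                p_value=p,
                cohens_d=d,
                shapiro_p=sw_p,
                ks_p=ks_p,
                flags=flags,
            )
        )
    return out


def pivot_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject change matrix (one column per outcome)."""
    t = table.copy()
    t["change"] = t["discharge"] - t["admission"]
    return t.pivot(index="subject_id", columns="outcome", values="change")


@dataclass
class RegressionStep:
    action: str  # "add" | "remove"
    predictor: str
    r2: float
    adj_r2: float
    r2_change: float
    f_stat: float
    p_value: float


@dataclass
class RegressionResult:
    response: str
    selected: list[str]
    steps: list[RegressionStep]
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    coefficients: pd.Series  # unstandardized B (incl. const)
    std_coefficients: pd.Series  # standardized beta per predictor
    vif: pd.Series
    residual_shapiro_p: float
    flags: list[str] = field(default_factory=list)


def _fit(y: np.ndarray, x: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()


def stepwise_regression(
    response: pd.Series,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionResult:
    """Forward selection with backward elimination on partial-F p-values.

    At each step the candidate with the smallest partial-F p-value below
    ``p_enter`` is added; any included predictor whose p-value has risen
    above ``p_remove`` is then removed; iterate to a fixed point.
    Complete-case rows only; perfectly collinear candidates are excluded
    with a warning.  Residual normality (Shapiro–Wilk) and VIFs validate
    the final model.
    """
    data = pd.concat([response.rename("__y__"), candidates], axis=1).dropna()
    y = data["__y__"].to_numpy()
    x_all = data.drop(columns="__y__")
    flags: list[str] = []

    # drop constant / perfectly collinear candidates up front
    usable: list[str] = []
    for c in x_all.columns:
        col = x_all[c].to_numpy()
        if np.ptp(col) == 0:
            flags.append(f"candidate {c!r} constant, excluded")
            continue
        if usable:
            sub = x_all[usable + [c]].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), sub])) <= len(usable) + 1:
                flags.append(f"candidate {c!r} perfectly collinear, excluded")
                warnings.warn(flags[-1], stacklevel=2)
                continue
        usable.append(c)

    selected: list[str] = []
    steps: list[RegressionStep] = []
    prev_r2 = 0.0
    y_var = float(np.var(y))
    while True:
        changed = False
        if selected:  # numerically perfect fit: nothing left to explain
            cur = _fit(y, x_all[selected])
            if cur.ssr <= 1e-12 * max(y_var, 1.0) * len(y):
                break
        # forward step
        best_p, best_c = np.inf, None
        for c in usable:
            if c in selected:
                continue
            fit = _fit(y, x_all[selected + [c]])
            p = fit.pvalues[c]
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            fit = _fit(y, x_all[selected])
            steps.append(
                RegressionStep(
                    "add", best_c, fit.rsquared, fit.rsquared_adj,
                    fit.rsquared - prev_r2, fit.fvalue, fit.f_pvalue,
                )
            )
            prev_r2 = fit.rsquared
            changed = True
        # backward step(s)
        while selected:
            fit = _fit(y, x_all[selected])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] <= p_remove:
                break
            selected.remove(worst)
            newfit = _fit(y, x_all[selected]) if selected else None
            r2 = newfit.rsquared if newfit is not None else 0.0
            steps.append(
                RegressionStep(
                    "remove", worst,
                    r2,
                    newfit.rsquared_adj if newfit is not None else 0.0,
                    r2 - prev_r2,
                    newfit.fvalue if newfit is not None else np.nan,
                    newfit.f_pvalue if newfit is not None else np.nan,
                )
            )
            prev_r2 = r2
            changed = True
        if not changed:
            break

    if not selected:
        flags.append("no candidate passed entry criterion; empty model")
        return RegressionResult(
            response=str(response.name), selected=[], steps=steps,
            r2=0.0, adj_r2=0.0, f_stat=np.nan, f_pvalue=np.nan,
            coefficients=pd.Series(dtype=float),
            std_coefficients=pd.Series(dtype=float),
            vif=pd.Series(dtype=float),
            residual_shapiro_p=np.nan, flags=flags,
        )

    fit = _fit(y, x_all[selected])
    resid = fit.resid
    sw_p = float(stats.shapiro(resid).pvalue) if len(resid) >= 3 else np.nan
    # standardized betas from z-scored response and predictors
    beta = pd.Series(
        {
            c: fit.params[c] * x_all[c].std(ddof=1) / np.std(y, ddof=1)
            for c in selected
        }
    )
    # VIF_j = 1/(1 - R²_j) regressing predictor j on the others; 1 for a sole predictor
    vif = {}
    for c in selected:
        others = [o for o in selected if o != c]
        if not others:
            vif[c] = 1.0
        else:
            r2j = _fit(x_all[c].to_numpy(), x_all[others]).rsquared
            vif[c] = 1.0 / (1.0 - r2j) if r2j < 1 else np.inf
    return RegressionResult(
        response=str(response.name),
        selected=selected,
        steps=steps,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        coefficients=fit.params,
        std_coefficients=beta,
        vif=pd.Series(vif),
        residual_shapiro_p=sw_p,
        flags=flags,
    )


@dataclass
class SampleSizeResult:
    outcome: str
    assumed_percent_change: float
    effect_size_d: float
    alpha: float
    power: float
    required_n: int


def _paired_t_power(n: int, d: float, alpha: float) -> float:
    """Power of the two-tailed one-sample (paired-difference) t-test."""
    df = n - 1
    nc = abs(d) * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = 1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(power):  # nct.cdf underflows at large noncentrality
        power = stats.norm.cdf(nc - tcrit) + stats.norm.cdf(-nc - tcrit)
    return float(power)


def sample_size_paired(
    baseline_mean: float,
    sd_change: float,
    percent_change: float,
    alpha: float = 0.05,
    power: float = 0.80,
    outcome: str = "",
) -> SampleSizeResult:
    """Smallest n whose noncentral-t power reaches the target.

    The assumed effect is ``percent_change`` of the baseline mean, scaled
    by the observed SD of change: d = (pct/100 · baseline) / SD(change).
    """
    if sd_change <= 0:
        raise ValueError("sd_change must be positive")
    d = (percent_change / 100.0) * baseline_mean / sd_change
    if d == 0:
        raise ValueError("zero effect size: required n is unbounded")
    n = 2
    while _paired_t_power(n, d, alpha) < power:
        n += 1
        if n > 1_000_000:
            raise RuntimeError("required n exceeds 1e6")
    return SampleSizeResult(
        outcome=outcome,
        assumed_percent_change=percent_change,
        effect_size_d=float(d),
        alpha=alpha,
        power=power,
        required_n=n,
    )


def sample_size_grid(
    summaries: list[ChangeSummary],
    percents: tuple[float, ...] = (10.0, 20.0, 30.0),
    alpha: float = 0.05,
    power: float = 0.80,
) -> pd.DataFrame:
    """The 10/20/30% sample-size grid over a set of outcomes."""
    rows = []
    for s in summaries:
        for pct in percents:
            if s.sd_change <= 0 or s.admission_mean == 0:
                continue
            r = sample_size_paired(
                abs(s.admission_mean), s.sd_change, pct, alpha, power, outcome=s.outcome
            )
            rows.append(
                {
                    "outcome": s.outcome,
                    "percent_change": pct,
                    "effect_size_d": r.effect_size_d,
                    "required_n": r.required_n,
                }
            )
    return pd.DataFrame(rows)
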