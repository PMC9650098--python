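"""Statistical layer: normality checks, outlier exclusion, ANOVA with
post-hoc tests, and power-based sample-size computation.

Conventions: Shapiro-Wilk for normality; a single-pass +/-2 SD rule for
outlier exclusion; one- and two-way between-subjects ANOVA (OLS), with a
mixed (between-group x within-time, subject as error stratum) ANOVA for the
time courses; Tukey or Bonferroni post-hoc comparisons; alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


def exclude_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass +/-2 SD exclusion.

    Mean and sample SD are computed once on all points; a point is excluded
    iff |x - mean| > 2*SD.  Returns (kept, excluded).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    mu = x.mean()
    sd = x.std(ddof=1)
    out = np.abs(x - mu) > 2.0 * sd
    return x[~out], x[out]


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value (n between 3 and 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    return float(sps.shapiro(x).pvalue)


@dataclass
class AnovaTerm:
    factor: str
    f_value: float
    df1: float
    df2: float
    p_value: float


@dataclass
class AnovaResult:
    """Omnibus terms plus post-hoc pairwise comparisons for one outcome."""

    outcome: str
    design: str  # "one-way" | "two-way" | "mixed"
    terms: list[AnovaTerm]
    posthoc: pd.DataFrame
    posthoc_method: str
    shapiro_p: float
    excluded: list[float] = field(default_factory=list)

    def term(self, factor: str) -> AnovaTerm:
        for t in self.terms:
            if t.factor == factor:
                return t
        raise KeyError(factor)

    def to_rows(self) -> list[dict]:
        return [
            {"outcome": self.outcome, "design": self.design, "factor": t.factor,
             "F": t.f_value, "df1": t.df1, "df2": t.df2, "p": t.p_value,
             "shapiro_p": self.shapiro_p, "n_excluded": len(self.excluded)}
            for t in self.terms
        ]


def _posthoc(df: pd.DataFrame, outcome: str, factor: str, method: str
             ) -> pd.DataFrame:
    if method == "tukey":
        res = pairwise_tukeyhsd(df[outcome], df[factor], alpha=ALPHA)
        tbl = pd.DataFrame(
            data=res._results_table.data[1:], columns=res._results_table.data[0])
        tbl = tbl.rename(columns={"p-adj": "p_adj", "group1": "a", "group2": "b"})
        return tbl[["a", "b", "meandiff", "p_adj"]]
    if method == "bonferroni":
        tbl = pg.pairwise_tests(data=df, dv=outcome, between=factor,
                                padjust="bonf")
        cols = {"A": "a", "B": "b"}
        tbl = tbl.rename(columns=cols)
        pcol = next(c for c in ("p_corr", "p-corr", "p_unc", "p-unc")
                    if c in tbl.columns)
        tbl["p_adj"] = tbl[pcol].clip(upper=1.0)
        return tbl[["a", "b", "p_adj"]]
    raise ValueError("posthoc must be 'tukey' or 'bonferroni'")


def run_anova(
    table: pd.DataFrame,
    outcome: str,
    factors: list[str],
    posthoc: str = "tukey",
    subject: str | None = None,
    screen_outliers: bool = True,
) -> AnovaResult:
    """Omnibus ANOVA with post-hoc pairwise comparisons.

    One factor -> one-way ANOVA; two between factors -> additive two-way
    ANOVA; two factors with ``subject`` given -> mixed ANOVA with the second
    factor treated as the repeated (within-subject) measure.  When
    ``screen_outliers`` is set, the +/-2 SD rule is applied within each cell
    of the first factor before fitting.  Post-hoc comparisons are computed on
    the first factor.
    """
    if len(factors) not in (1, 2):
        raise ValueError("factors must name 1 or 2 columns")
    df = table.dropna(subset=[outcome, *factors]).copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if df.groupby(list(factors)).size().min() < 2:
        raise ValueError("insufficient replication within cells")

    excluded: list[float] = []
    if screen_outliers:
        keep_idx = []
        for _, sub in df.groupby(factors[0]):
            if len(sub) >= 3:
                _, out = exclude_outliers(sub[outcome].to_numpy())
                excluded.extend(out.tolist())
                keep_idx.extend(sub.index[~sub[outcome].isin(out)].tolist())
            else:
                keep_idx.extend(sub.index.tolist())
        df = df.loc[sorted(keep_idx)]

    shapiro_p = shapiro_wilk(df[outcome]) if 3 <= len(df) <= 5000 else float("nan")

    terms: list[AnovaTerm] = []
    if len(factors) == 2 and subject is not None:
        design = "mixed"
        aov = pg.mixed_anova(data=df, dv=outcome, between=factors[0],
                             within=factors[1], subject=subject)
        for _, r in aov.iterrows():
            if r["Source"] == "Interaction":
                name = f"{factors[0]}*{factors[1]}"
            else:
                name = str(r["Source"])
            pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
            terms.append(AnovaTerm(name, float(r["F"]), float(r["DF1"]),
                                   float(r["DF2"]), float(r[pcol])))
        design_df = df
    elif len(factors) == 2:
        design = "two-way"
        model = ols(f"Q('{outcome}') ~ C(Q('{factors[0]}')) + C(Q('{factors[1]}'))",
                    data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        resid_df = float(aov.loc["Residual", "df"])
        for f in factors:
            row = aov.loc[f"C(Q('{f}'))"]
            terms.append(AnovaTerm(f, float(row["F"]), float(row["df"]),
                                   resid_df, float(row["PR(>F)"])))
        design_df = df
    else:
        design = "one-way"
        f = factors[0]
        model = ols(f"Q('{outcome}') ~ C(Q('{f}'))", data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        row = aov.loc[f"C(Q('{f}'))"]
        terms.append(AnovaTerm(f, float(row["F"]), float(row["df"]),
                               float(aov.loc["Residual", "df"]),
                               float(row["PR(>F)"])))
        design_df = df

    ph = _posthoc(design_df, outcome, factors[0], posthoc)
    return AnovaResult(outcome=outcome, design=design, terms=terms, posthoc=ph,
                       posthoc_method=posthoc, shapiro_p=shapiro_p,
                       excluded=excluded)


def power_n_per_group(
    reference_mean: float,
    reference_sd: float,
    detectable_fraction: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 10000,
) -> int:
    """Smallest per-group n detecting a difference of ``detectable_fraction``
    of the reference mean with a two-sided two-sample t-test.

    Iterates the exact noncentral-t power expression upward from n = 2.
    """
    if min(reference_mean, reference_sd, detectable_fraction, alpha) <= 0:
        raise ValueError("all inputs must be positive")
    if not 0 < detectable_fraction <= 1:
        raise ValueError("detectable_fraction must lie in (0, 1]")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    d = detectable_fraction * reference_mean / reference_sd
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        achieved = (1.0 - sps.nct.cdf(tcrit, df, nc)
                    + sps.nct.cdf(-tcrit, df, nc))
        if achieved >= power:
            return n
    raise ValueError("no n below n_max reaches the requested power")


def make_report(
    trace_table: pd.DataFrame,
    trace_long: pd.DataFrame | None = None,
    nmj_table: pd.DataFrame | None = None,
    posthoc: str = "tukey",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus ANOVA table and post-hoc table across the study's outcomes.

    Trace outcomes (specific force, initial/final NMTF, final intratrain
    fatigue) get one-way group ANOVAs; the NMTF time course gets a mixed
    group x time ANOVA; NMJ outcomes, when given, get group x fiber-type
    two-way ANOVAs on per-animal-per-class means.
    """
    rows: list[dict] = []
    ph_rows: list[pd.DataFrame] = []

    def add(*args, **kwargs) -> None:
        try:
            result = run_anova(*args, **kwargs)
        except ValueError:
            # outcome not testable under this design (e.g. too few levels or
            # no replication within cells); the rest of the report proceeds
            return
        rows.extend(result.to_rows())
        ph = result.posthoc.copy()
        ph.insert(0, "outcome", result.outcome)
        ph.insert(1, "method", result.posthoc_method)
        ph_rows.append(ph)

    for outcome in ["specific_force_n_per_cm2", "initial_nmtf_pct",
                    "final_nmtf_pct", "final_intratrain_fatigue_pct"]:
        if outcome in trace_table.columns:
            add(trace_table, outcome, ["group"], posthoc=posthoc)

    if trace_long is not None and len(trace_long):
        for outcome in ["nmtf_pct", "intratrain_fatigue_pct"]:
            if outcome in trace_long.columns:
                sub = trace_long[trace_long["epoch_s"] > 0]
                add(sub, outcome, ["group", "epoch_s"],
                    posthoc="bonferroni", subject="animal_id",
                    screen_outliers=False)

    if nmj_table is not None and len(nmj_table):
        for outcome in ["apposition_pct", "relative_planar_area_pct",
                        "terminal_csa_um2", "endplate_csa_um2"]:
            if outcome in nmj_table.columns and "fiber_type_class" in nmj_table.columns:
                add(nmj_table, outcome, ["group", "fiber_type_class"],
                    posthoc="bonferroni", screen_outliers=False)

    report = pd.DataFrame(rows)
    posthoc_tbl = (pd.concat(ph_rows, ignore_index=True)
                   if ph_rows else pd.DataFrame())
    return report, posthoc_tbl
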