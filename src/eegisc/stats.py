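"""Group-comparison and covariate statistics for ISC analyses.

The battery mirrors what a two-group naturalistic-EEG study needs: Welch's
two-sample t-test with Cohen's d, a one-covariate ANCOVA with eta-squared
effect size and covariate-adjusted (Bonferroni) marginal means, Pearson and
tie-corrected Kendall correlations, a one-tailed one-sample Wilcoxon
signed-rank test with the r = |Z|/sqrt(n) effect size, and assembly/fitting
of the mixed-effects long table relating windowed ISC to movement content
and clinical scores (REML fitting is delegated to statsmodels).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    """A single reported statistic with its p-value and effect size."""

    name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    effect_size_name: str | None = None
    effect_size: float | None = None
    adjustment: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Welch's t and Cohen's d


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled-SD convention (n-1 denominators)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return (a.mean() - b.mean()) / sp


def welch_t(a, b, alternative: str = "two-sided") -> StatResult:
    """Welch's unequal-variance t-test with Satterthwaite df and Cohen's d."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = ss.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return StatResult(
        name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        effect_size_name="cohen_d",
        effect_size=cohen_d(a, b),
    )


# ---------------------------------------------------------------------------
# ANCOVA


def _eta_squared(ss_effect: float, ss_error: float, ss_observed: float = 0.0) -> float:
    return ss_effect / (ss_effect + ss_observed + ss_error)


def ancova_group_cov(
    y, group, cov, observed_covariate: bool = False
) -> dict[str, StatResult]:
    """One-covariate ANCOVA of a two-group outcome.

    Fits ``y ~ group + cov`` (Type-II sums of squares) and, separately,
    ``y ~ group * cov`` for the interaction.  Returns the group effect with
    generalized eta-squared, the interaction effect, and covariate-adjusted
    group means at the grand covariate mean with Bonferroni-adjusted
    pairwise p.  With ``observed_covariate`` the covariate's SS joins the
    eta-squared denominator (the observed-factor convention); the default
    excludes it.
    """
    frame = pd.DataFrame(
        {"y": np.asarray(y, float), "g": np.asarray(group), "x": np.asarray(cov, float)}
    )
    if frame["g"].nunique() != 2:
        raise ValueError("exactly two groups required")
    if frame.shape[0] <= 4:
        raise ValueError("too few observations for ANCOVA")
    constant_cov = frame["x"].nunique() == 1
    if constant_cov:
        logger.warning("constant covariate: reducing to one-way ANOVA")
        main = smf.ols("y ~ C(g)", data=frame).fit()
    else:
        main = smf.ols("y ~ C(g) + x", data=frame).fit()
    table = anova_lm(main, typ=2)
    ss_g = float(table.loc["C(g)", "sum_sq"])
    ss_err = float(table.loc["Residual", "sum_sq"])
    ss_obs = float(table.loc["x", "sum_sq"]) if (observed_covariate and not constant_cov) else 0.0
    out: dict[str, StatResult] = {}
    out["group"] = StatResult(
        name="ancova_group",
        statistic=float(table.loc["C(g)", "F"]),
        p_value=float(table.loc["C(g)", "PR(>F)"]),
        df=(float(table.loc["C(g)", "df"]), float(table.loc["Residual", "df"])),
        effect_size_name="generalized_eta_squared",
        effect_size=_eta_squared(ss_g, ss_err, ss_obs),
        extra={"ss": {k: float(table.loc[k, "sum_sq"]) for k in table.index}},
    )

    if not constant_cov:
        inter = smf.ols("y ~ C(g) * x", data=frame).fit()
        itab = anova_lm(inter, typ=2)
        key = "C(g):x"
        out["interaction"] = StatResult(
            name="ancova_interaction",
            statistic=float(itab.loc[key, "F"]),
            p_value=float(itab.loc[key, "PR(>F)"]),
            df=(float(itab.loc[key, "df"]), float(itab.loc["Residual", "df"])),
            effect_size_name="generalized_eta_squared",
            effect_size=_eta_squared(
                float(itab.loc[key, "sum_sq"]), float(itab.loc["Residual", "sum_sq"])
            ),
        )

    # covariate-adjusted marginal means at the grand covariate mean
    levels = sorted(frame["g"].unique())
    grand = frame["x"].mean()
    adj = {}
    for lev in levels:
        pred = pd.DataFrame({"g": [lev], "x": [grand]})
        adj[str(lev)] = float(main.predict(pred).iloc[0])
    # two groups -> one pairwise comparison; Bonferroni factor 1
    n_comp = len(levels) * (len(levels) - 1) // 2
    pair_p = min(1.0, float(main.pvalues["C(g)[T.%s]" % levels[1]]) * n_comp)
    out["adjusted_means"] = StatResult(
        name="adjusted_means",
        statistic=adj[str(levels[1])] - adj[str(levels[0])],
        p_value=pair_p,
        adjustment="bonferroni",
        extra={"means": adj},
    )
    return out


# ---------------------------------------------------------------------------
# Correlations


def pearson_r(x, y) -> StatResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero variance: Pearson correlation undefined")
        return StatResult(name="pearson_r", statistic=float("nan"), p_value=float("nan"))
    res = ss.pearsonr(x, y)
    return StatResult(
        name="pearson_r", statistic=float(res.statistic), p_value=float(res.pvalue),
        df=float(x.size - 2),
    )


def kendall_tau(x, y) -> StatResult:
    """Kendall's tau-b (tie-corrected); exact p for small tie-free samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("zero variance: Kendall correlation undefined")
        return StatResult(name="kendall_tau", statistic=float("nan"), p_value=float("nan"))
    has_ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    method = "exact" if (x.size <= 8 and not has_ties) else "asymptotic"
    res = ss.kendalltau(x, y, variant="b", method=method)
    return StatResult(
        name="kendall_tau", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def wilcoxon_one_sample(x, alternative: str = "greater") -> StatResult:
    """One-sample Wilcoxon signed-rank test against zero.

    Exact p for n <= 25 (no ties in |x|), normal approximation with
    continuity correction otherwise.  Effect size r = |Z|/sqrt(n) with Z
    from the (tie-corrected) normal approximation, n the number of non-zero
    observations.
    """
    x = np.asarray(x, float)
    x = x[x != 0]
    n = x.size
    if n < 5:
        raise ValueError("need at least five non-zero observations")
    mode = "exact" if n <= 25 else "approx"
    try:
        res = ss.wilcoxon(x, alternative=alternative, method=mode, correction=True)
    except ValueError:          # ties in |x| forbid the exact distribution
        res = ss.wilcoxon(x, alternative=alternative, method="approx", correction=True)

    # Z from the normal approximation (tie-corrected variance)
    ranks = ss.rankdata(np.abs(x))
    w_plus = ranks[x > 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(x), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = (w_plus - mu) / math.sqrt(var)
    return StatResult(
        name="wilcoxon_one_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_name="r",
        effect_size=abs(z) / math.sqrt(n),
        extra={"z": z, "n": n},
    )


# ---------------------------------------------------------------------------
# Mixed model on windowed ISC


def _sanitize(name: str) -> str:
    return re.sub(r"\W+", "_", name.strip()).strip("_").lower()


def build_mixed_table(
    aligned: pd.DataFrame,
    score_columns: list[str] | None = None,
    outcome: str = "topk_sum",
) -> tuple[pd.DataFrame, str]:
    """Prepare the model-ready long table and the fixed-effects formula.

    The fixed effects are the movement label, the clinical/cognitive scores
    and the score-by-movement interactions; rows with missing values are
    dropped.  Returns ``(table, formula)``; random effects (subject
    intercept and subject-by-movement slope) are specified at fit time.
    """
    table = aligned.copy()
    if "movement" not in table.columns:
        raise ValueError("aligned table lacks a 'movement' column")
    if score_columns is None:
        reserved = {
            "subject", "group", "video", "window", "t_start", "t_end",
            outcome, "movement",
        }
        score_columns = [
            c for c in table.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(table[c])
        ]
    rename = {c: _sanitize(c) for c in score_columns}
    table = table.rename(columns=rename)
    scores = list(rename.values())
    table = table.dropna(subset=[outcome, "movement", *scores]).reset_index(drop=True)

    movement_levels = table["movement"].nunique()
    if movement_levels < 2:
        logger.warning("single movement level: movement terms dropped")
        terms = scores or ["1"]
    else:
        # no-movement windows are the natural baseline for the contrasts
        mv = (
            "C(movement, Treatment('neither'))"
            if (table["movement"] == "neither").any()
            else "C(movement)"
        )
        terms = [mv] + scores + [f"{mv}:{s}" for s in scores]
    formula = f"{outcome} ~ " + " + ".join(terms) if terms else f"{outcome} ~ 1"
    return table, formula


def fit_mixed(
    aligned: pd.DataFrame,
    score_columns: list[str] | None = None,
    outcome: str = "topk_sum",
    random_movement_slope: bool = True,
) -> tuple[dict[str, StatResult], object]:
    """REML mixed model of windowed ISC (statsmodels MixedLM).

    Random effects: per-subject intercept and, when the movement factor has
    at least two levels, a per-subject movement slope.  Returns per-term
    Wald statistics and the fitted statsmodels results object.
    """
    table, formula = build_mixed_table(aligned, score_columns, outcome)
    has_movement = "C(movement)" in formula
    re_formula = "~C(movement)" if (random_movement_slope and has_movement) else "1"
    model = smf.mixedlm(formula, data=table, groups=table["subject"], re_formula=re_formula)
    try:
        fit = model.fit(reml=True)
    except Exception as exc:
        logger.warning("random-slope fit failed (%s); refitting intercept-only", exc)
        model = smf.mixedlm(formula, data=table, groups=table["subject"], re_formula="1")
        fit = model.fit(reml=True)
    results = {}
    for term in fit.fe_params.index:
        results[term] = StatResult(
            name=term,
            statistic=float(fit.tvalues[term]),
            p_value=float(fit.pvalues[term]),
            extra={"estimate": float(fit.fe_params[term]), "se": float(fit.bse[term])},
        )
    return results, fit


def results_frame(results: dict[str, StatResult]) -> pd.DataFrame:
    """Tidy TSV-ready frame of StatResults."""
    rows = []
    for key, r in results.items():
        df = r.df
        rows.append(
            {
                "term": key,
                "test": r.name,
                "statistic": r.statistic,
                "df": str(df) if df is not None else "",
                "p": r.p_value,
                "effect_size_name": r.effect_size_name or "",
                "effect_size": r.effect_size if r.effect_size is not None else "",
                "adjustment": r.adjustment or "",
            }
        )
    return pd.DataFrame(rows)
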