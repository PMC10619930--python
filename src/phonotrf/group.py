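"""Group-level statistical models linking prediction accuracy to age.

The layer mirrors the analysis structure of cross-sectional infant TRF
studies: linear mixed models of prediction accuracy with age and language
condition (native coded -0.5) as fixed effects and participant (and, for
per-feature analyses, feature identity) as random intercepts; a
divergence-age estimate from the pointwise 95% CI of the fitted age
trajectory of an accuracy difference; and a sex-balanced bootstrap for
interaction terms.

Degrees of freedom: t tests use the residual-df approximation
(``df_method='residual'`` in every result) since the numerics stack does
not provide Satterthwaite df for mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

DF_METHOD = "residual"


@dataclass
class ModelResult:
    """Tidy fixed-effects table plus fit metadata."""

    terms: pd.DataFrame          # index term; estimate, se, t, df, p
    loglik: float
    n_obs: int
    df_method: str = DF_METHOD
    extras: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]


def _fit_mixed(formula: str, data: pd.DataFrame, groups: str | None,
               vc_formula: dict | None = None, reml: bool = True):
    if groups is None:
        data = data.assign(_all=1)
        groups = "_all"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups],
                            re_formula="1" if vc_formula is None else "0",
                            vc_formula=vc_formula)
        return model.fit(reml=reml)


def _terms_table(result, n_obs: int) -> pd.DataFrame:
    fe = result.fe_params
    se = result.bse_fe
    t = fe / se
    df = max(n_obs - len(fe), 1)
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"estimate": fe, "se": se, "t": t,
                         "df": float(df), "p": p})


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["age_c"] = df["age_months"] - df["age_months"].mean()
    if "r_baseline" in df:
        df["diff_rb"] = df["r_observed"] - df["r_baseline"]
    if "sex" in df:
        df["sex_code"] = np.where(df["sex"].astype(str).str.upper().str.startswith("F"),
                                  -0.5, 0.5)
    return df


# ---------------------------------------------------------------------------
# Condition x age
# ---------------------------------------------------------------------------

def fit_condition_age_model(records: pd.DataFrame, dep: str = "r_observed") -> ModelResult:
    """LMM ``r ~ age_c * condition_code + (1 | participant)``.

    Extras carry the per-condition simple slopes (age effect with the
    respective condition at the reference level).
    """
    df = _prepare(records)
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants for a random intercept")
    if df.groupby("participant")["condition_code"].nunique().min() < 2:
        raise ValueError("need both conditions for every participant")
    res = _fit_mixed(f"{dep} ~ age_c * condition_code", df, groups="participant")
    terms = _terms_table(res, len(df))

    slopes = {}
    for cond, code in (("native", -0.5), ("nonnative", 0.5)):
        shifted = df.assign(cond0=df["condition_code"] - code)
        r = _fit_mixed(f"{dep} ~ age_c * cond0", shifted, groups="participant")
        tab = _terms_table(r, len(df))
        slopes[cond] = tab.loc["age_c"]
    return ModelResult(terms, float(res.llf), len(df),
                       extras={"simple_slopes": slopes})


def divergence_age(
    records: pd.DataFrame,
    pairing: str = "condition",
    alpha: float = 0.05,
    grid_step_months: float = 1.0,
) -> float | None:
    """Earliest age at which the fitted accuracy difference exceeds zero.

    The per-participant difference (native - non-native accuracy, or
    observed - baseline for ``pairing='baseline'``) is regressed on age; the
    pointwise (1-alpha) CI of the conditional mean is evaluated on a
    1-month grid over the observed age range, and the smallest age whose
    lower bound exceeds 0 is returned (``None`` if there is none).
    """
    df = _prepare(records)
    if pairing == "condition":
        nat = df[df["condition_code"] < 0].set_index("participant")
        non = df[df["condition_code"] > 0].set_index("participant")
        common = nat.index.intersection(non.index)
        diff = nat.loc[common, "r_observed"] - non.loc[common, "r_observed"]
        ages = nat.loc[common, "age_months"]
    elif pairing == "baseline":
        sub = df[df["condition_code"] < 0] if "condition_code" in df else df
        diff = (sub["r_observed"] - sub["r_baseline"]).to_numpy()
        ages = sub["age_months"].to_numpy()
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    diff = np.asarray(diff, dtype=float)
    ages = np.asarray(ages, dtype=float)
    X = sm.add_constant(ages)
    fit = sm.OLS(diff, X).fit()
    grid = np.arange(np.floor(ages.min()), np.ceil(ages.max()) + 0.5,
                     grid_step_months)
    pred = fit.get_prediction(sm.add_constant(grid))
    lower = pred.conf_int(alpha=alpha)[:, 0]
    above = np.flatnonzero(lower > 0)
    return float(grid[above[0]]) if above.size else None


# ---------------------------------------------------------------------------
# Feature timing / pitch similarity
# ---------------------------------------------------------------------------

_TIMING_RHS = "age_c * duration_rank + occurrence_rank"


def _check_feature_table(df: pd.DataFrame) -> None:
    for col in ("duration_rank", "occurrence_rank"):
        if df[col].nunique() < 2:
            raise ValueError(f"column {col!r} is constant; model unidentified")


def fit_feature_timing_model(records: pd.DataFrame, reml: bool = True) -> ModelResult:
    """LMM ``(r_obs - r_base) ~ age_c*duration_rank + occurrence_rank``
    with crossed random intercepts for participant and feature."""
    df = _prepare(records)
    _check_feature_table(df)
    vc = {"participant": "0 + C(participant)", "feature": "0 + C(feature)"}
    res = _fit_mixed(f"diff_rb ~ {_TIMING_RHS}", df, groups=None,
                     vc_formula=vc, reml=reml)
    return ModelResult(_terms_table(res, len(df)), float(res.llf), len(df))


def fit_pitch_similarity_model(records: pd.DataFrame,
                               lr_test: bool = True) -> ModelResult:
    """Extend the timing model with ``age_c * pitch_similarity_rank``.

    Wald t values come from the REML fit.  With ``lr_test`` the duration-only
    and full models are refit by maximum likelihood (REML is invalid for LR
    tests on fixed effects) and extras carry the likelihood-ratio comparison
    plus the variance inflation factors of the fixed-effect design.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    df = _prepare(records)
    _check_feature_table(df)
    vc = {"participant": "0 + C(participant)", "feature": "0 + C(feature)"}
    full_rhs = f"{_TIMING_RHS} + age_c * pitch_similarity_rank"

    import patsy as _patsy
    Xfull = _patsy.dmatrix(full_rhs, df)
    Xbase = _patsy.dmatrix(_TIMING_RHS, df)
    if np.linalg.matrix_rank(Xfull) == np.linalg.matrix_rank(Xbase):
        # pitch rank carries no information beyond the duration terms
        # (e.g. identical columns): the model spaces coincide
        base = fit_feature_timing_model(records)
        base.extras = {"lr_stat": 0.0, "lr_df": 2, "lr_p": 1.0,
                       "vif": {"pitch_similarity_rank": float("inf"),
                               "age_c:pitch_similarity_rank": float("inf")},
                       "base_loglik": base.loglik,
                       "collinear": True}
        return base

    full = _fit_mixed(f"diff_rb ~ {full_rhs}", df, groups=None,
                      vc_formula=vc, reml=True)
    extras: dict = {}
    if lr_test:
        base_ml = _fit_mixed(f"diff_rb ~ {_TIMING_RHS}", df, groups=None,
                             vc_formula=vc, reml=False)
        full_ml = _fit_mixed(f"diff_rb ~ {full_rhs}", df, groups=None,
                             vc_formula=vc, reml=False)
        lr = 2 * (full_ml.llf - base_ml.llf)
        df_diff = len(full_ml.fe_params) - len(base_ml.fe_params)
        import patsy
        X = patsy.dmatrix(full_rhs, df, return_type="dataframe")
        cols = [c for c in X.columns if c != "Intercept"]
        vif = {c: float(variance_inflation_factor(X[cols].to_numpy(), i))
               for i, c in enumerate(cols)}
        extras = {"lr_stat": float(lr), "lr_df": int(df_diff),
                  "lr_p": float(stats.chi2.sf(max(lr, 0.0), df_diff)),
                  "vif": vif, "base_loglik": float(base_ml.llf)}
    return ModelResult(_terms_table(full, len(df)), float(full.llf), len(df),
                       extras=extras)


# ---------------------------------------------------------------------------
# Bootstrap and age-shape comparison
# ---------------------------------------------------------------------------

def balanced_bootstrap_ci(
    records: pd.DataFrame,
    interaction_terms: tuple[str, ...] = ("age_c:sex_code",
                                          "age_c:condition_code:sex_code"),
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentile CIs of interaction t values over sex-balanced resamples.

    Each resample draws, with replacement, equal numbers of female and male
    participants totalling the original N, refits
    ``r ~ age_c * condition_code * sex_code + (1 | participant)`` and stores
    the t value of each requested interaction term.  Returns per-term 2.5/
    97.5 percentile bounds and the fraction of resamples where |t| > the
    nominal critical value.
    """
    rng = np.random.default_rng(rng)
    df = _prepare(records)
    by_sex = {s: df.loc[df["sex_code"] == s, "participant"].unique()
              for s in (-0.5, 0.5)}
    if any(len(v) == 0 for v in by_sex.values()):
        raise ValueError("both sexes must be present")
    n_total = df["participant"].nunique()
    n_half = n_total // 2

    t_store: dict[str, list[float]] = {t: [] for t in interaction_terms}
    for b in range(n_boot):
        chosen = np.concatenate([
            rng.choice(by_sex[-0.5], size=n_half, replace=True),
            rng.choice(by_sex[0.5], size=n_total - n_half, replace=True),
        ])
        parts = []
        for k, pid in enumerate(chosen):
            sub = df[df["participant"] == pid].copy()
            sub["participant"] = f"b{k:03d}"
            parts.append(sub)
        boot = pd.concat(parts, ignore_index=True)
        try:
            res = _fit_mixed("r_observed ~ age_c * condition_code * sex_code",
                             boot, groups="participant")
            tab = _terms_table(res, len(boot))
            for term in interaction_terms:
                t_store[term].append(float(tab.loc[term, "t"]))
        except Exception:
            continue
    crit = stats.norm.ppf(1 - alpha / 2)
    out = []
    for term, ts in t_store.items():
        ts = np.asarray(ts)
        out.append({
            "term": term,
            "ci_lo": float(np.percentile(ts, 100 * alpha / 2)),
            "ci_hi": float(np.percentile(ts, 100 * (1 - alpha / 2))),
            "frac_significant": float(np.mean(np.abs(ts) > crit)),
            "n_resamples": ts.size,
        })
    return pd.DataFrame(out).set_index("term")


def compare_age_shapes(records: pd.DataFrame, dep: str = "r_observed") -> pd.DataFrame:
    """Likelihood-ratio tests for log/quadratic/cubic age terms.

    The linear LMM ``dep ~ age_c * condition_code + (1|participant)`` is
    compared (ML fits) against versions adding each non-linear age term.
    """
    df = _prepare(records)
    if df["age_months"].nunique() <= 2:
        raise ValueError("age must span more than 2 distinct values")
    df["log_age"] = np.log(df["age_months"])
    df["age_c2"] = df["age_c"] ** 2
    df["age_c3"] = df["age_c"] ** 3
    base_formula = f"{dep} ~ age_c * condition_code"
    base = _fit_mixed(base_formula, df, groups="participant", reml=False)
    rows = []
    for name, term in (("log", "log_age"), ("quadratic", "age_c2"),
                       ("cubic", "age_c3")):
        full = _fit_mixed(f"{base_formula} + {term}", df, groups="participant",
                          reml=False)
        lr = max(2 * (full.llf - base.llf), 0.0)
        rows.append({"shape": name, "lr_stat": float(lr),
                     "p": float(stats.chi2.sf(lr, 1))})
    return pd.DataFrame(rows).set_index("shape")
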