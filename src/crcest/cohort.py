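"""Cohort-level statistics for CrCEST outcomes.

One row per (subject, muscle) with the three imaging endpoints and
clinical covariates.  The statistical layer mirrors a standard
repeated-measures muscle-imaging analysis:

* Shapiro–Wilk normality screening and two-group Kruskal–Wallis rank
  comparisons for the univariate summaries;
* linear mixed-effects models (random intercept per subject, REML) for
  outcomes analysed across muscles, with the lateral gastrocnemius as the
  reference level;
* a likelihood-ratio screen for a disease × muscle interaction, after
  which per-muscle ordinary least squares model suites are fitted.

Fixed-effect p-values and confidence intervals use the Wald normal
approximation.  No multiple-testing correction is applied; significance
is two-sided p < 0.05 throughout.

A synthetic cohort generator with known injected effects makes the whole
layer testable by parameter recovery: its default group medians and
dispersions are the healthy-adult / Friedreich-ataxia values the package
is designed around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "CohortModel",
    "generate_cohort",
    "test_normality",
    "compare_groups_rank",
    "fit_mixed_model",
    "detect_interaction",
    "fit_linear_models_per_muscle",
    "summarize_cohort",
    "MIXED_SUITES",
    "OLS_SUITES",
    "CONTROL_MEDIANS",
    "FRDA_MEDIANS",
    "SingularFitError",
    "RankDeficiencyError",
    "MissingColumnError",
]

MUSCLES = ("LG", "MG", "Sol")
OUTCOMES = ("resting_pct", "delta_pct", "tau_s")

#: healthy-adult group medians per muscle (resting %, Δ %, τ s)
CONTROL_MEDIANS = {
    "resting_pct": {"LG": 6.2, "MG": 5.9, "Sol": 6.6},
    "delta_pct": {"LG": 8.9, "MG": 5.0, "Sol": 3.4},
    "tau_s": {"LG": 138.0, "MG": 184.0, "Sol": 254.0},
}

#: Friedreich-ataxia group medians per muscle
FRDA_MEDIANS = {
    "resting_pct": {"LG": 5.9, "MG": 6.3, "Sol": 7.0},
    "delta_pct": {"LG": 5.2, "MG": 3.5, "Sol": 3.9},
    "tau_s": {"LG": 274.0, "MG": 269.0, "Sol": 210.0},
}

#: total outcome SDs matched to the interquartile widths of the observed
#: distributions (IQR / 1.349), split evenly between the subject random
#: intercept and the residual
OUTCOME_SD = {"resting_pct": 1.5, "delta_pct": 2.0, "tau_s": 105.0}

#: additional covariates each named model admits, on top of the base
#: age + sex + disease (+ muscle for mixed models) block
MIXED_SUITES = {
    "resting_pct": {
        "Model 1": [],
        "Model 2": ["bmi"],
        "Model 3": ["height", "leg_lean_mass"],
        "Model 4": ["height", "leg_fat_mass"],
    },
    "delta_pct": {"Model 1": []},
    "tau_s": {"Model 1": []},
}

OLS_SUITES = {
    "delta_pct": {
        "Model 1": [],
        "Model 2": ["total_activity"],
        "Model 3": ["waist_cm"],
    },
    "tau_s": {
        "Model 1": [],
        "Model 2": ["delta_pct", "resting_pct"],
        "Model 3": ["total_activity"],
    },
    "resting_pct": {"Model 1": []},
}

BASE_COVARIATES = ["age", "sex", "disease"]


class SingularFitError(RuntimeError):
    """Mixed-model fit is singular or otherwise unidentifiable."""


class RankDeficiencyError(ValueError):
    """OLS design matrix is rank-deficient (collinear covariates)."""


class MissingColumnError(KeyError):
    """Cohort table lacks columns a requested model needs."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "cohort table is missing required column(s): "
            + ", ".join(self.missing)
        )


@dataclass
class ModelResult:
    """Fixed-effect estimates of one fitted model.

    `terms` has one row per coefficient: term, beta, ci_low, ci_high, p.
    """

    outcome: str
    model: str
    terms: pd.DataFrame
    n_subjects: int
    n_observations: int
    muscle: str | None = None
    kind: str = "mixed"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.terms[
            (self.terms["ci_low"] > self.terms["beta"])
            | (self.terms["ci_high"] < self.terms["beta"])
        ]
        if len(bad):
            raise ValueError("confidence interval does not bracket estimate")
        if self.n_observations > 3 * self.n_subjects:
            raise ValueError("more than 3 muscle rows per subject")

    def beta(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if not len(row):
            raise KeyError(term)
        return float(row["beta"].iloc[0])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms[self.terms["term"] == term]
        if not len(row):
            raise KeyError(term)
        return float(row["ci_low"].iloc[0]), float(row["ci_high"].iloc[0])

    def pvalue(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if not len(row):
            raise KeyError(term)
        return float(row["p"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        df = self.terms.copy()
        df.insert(0, "outcome", self.outcome)
        df.insert(1, "model", self.model)
        df.insert(2, "muscle", self.muscle or "all")
        df["n_subjects"] = self.n_subjects
        df["n_observations"] = self.n_observations
        return df

    def summary(self) -> str:
        head = (
            f"{self.kind} model — outcome {self.outcome}, {self.model}"
            + (f", muscle {self.muscle}" if self.muscle else "")
            + f" (n_subj={self.n_subjects}, n_obs={self.n_observations})"
        )
        body = self.terms.to_string(
            index=False,
            formatters={
                "beta": "{:9.3f}".format,
                "ci_low": "{:9.3f}".format,
                "ci_high": "{:9.3f}".format,
                "p": "{:9.4f}".format,
            },
        )
        return head + "\n" + body


# ---------------------------------------------------------------------------
# synthetic cohort generation


def _disease_effects_from_medians() -> dict:
    return {
        outc: {m: FRDA_MEDIANS[outc][m] - CONTROL_MEDIANS[outc][m]
               for m in MUSCLES}
        for outc in OUTCOMES
    }


def generate_cohort(
    n_control: int = 22,
    n_frda: int = 10,
    seed: int = 0,
    disease_effects: dict | None = None,
    subject_sd: dict | None = None,
    residual_sd: dict | None = None,
    control_medians: dict | None = None,
) -> pd.DataFrame:
    """Synthetic (subject, muscle) cohort table with known injected effects.

    Outcomes are generated additively: control muscle median + disease
    effect (for FRDA rows) + subject random intercept + residual, with the
    two noise components each at SD/√2 of the outcome's observed
    dispersion.  `disease_effects` maps outcome → muscle → shift; pass
    zeros for a null cohort.  Covariates are drawn to match the cohort
    characteristics the defaults are built around (age ≈ 29 y, BMI higher
    and activity lower in FRDA, …).
    """
    rng = np.random.default_rng(seed)
    if disease_effects is None:
        disease_effects = _disease_effects_from_medians()
    medians = {
        outc: {**CONTROL_MEDIANS[outc], **(control_medians or {}).get(outc, {})}
        for outc in OUTCOMES
    }
    subject_sd = subject_sd or {k: v / np.sqrt(2) for k, v in OUTCOME_SD.items()}
    residual_sd = residual_sd or {k: v / np.sqrt(2) for k, v in OUTCOME_SD.items()}

    rows = []
    n_total = n_control + n_frda
    for i in range(n_total):
        disease = "control" if i < n_control else "FRDA"
        sid = f"S{i + 1:03d}"
        age = float(np.clip(rng.normal(30.0, 7.0), 18, 65))
        sex = "F" if rng.uniform() < 0.42 else "M"
        if disease == "control":
            bmi = rng.normal(24.4, 3.0)
            waist = rng.normal(93.0, 8.0)
            activity = max(rng.normal(20.0, 8.0), 0.0)
        else:
            bmi = rng.normal(26.9, 3.0)
            waist = rng.normal(99.0, 10.0)
            activity = max(rng.normal(10.0, 5.0), 0.0)
        height = rng.normal(175.0, 8.0) if sex == "M" else rng.normal(162.0, 7.0)
        leg_lean = rng.normal(9.0, 1.5)
        leg_fat = max(rng.normal(3.5, 1.2), 0.5)
        intercepts = {
            outc: rng.normal(0.0, subject_sd[outc]) for outc in OUTCOMES
        }
        for muscle in MUSCLES:
            row = {
                "subject": sid,
                "disease": disease,
                "sex": sex,
                "age": age,
                "muscle": muscle,
                "bmi": float(bmi),
                "waist_cm": float(waist),
                "total_activity": float(activity),
                "height": float(height),
                "leg_lean_mass": float(leg_lean),
                "leg_fat_mass": float(leg_fat),
                "status": "ok",
            }
            for outc in OUTCOMES:
                mean = medians[outc][muscle]
                if disease == "FRDA":
                    mean += disease_effects.get(outc, {}).get(muscle, 0.0)
                val = (
                    mean
                    + intercepts[outc]
                    + rng.normal(0.0, residual_sd[outc])
                )
                if outc != "tau_s":
                    val = max(val, 0.0)
                else:
                    val = max(val, 1.0)
                row[outc] = float(val)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate statistics


def test_normality(values) -> float:
    """Shapiro–Wilk p-value for the normality of a sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no defined normality test")
    return float(stats.shapiro(x).pvalue)


def compare_groups_rank(values_a, values_b) -> tuple[float, float]:
    """Two-group Kruskal–Wallis statistic and p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.kruskal(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model fitting


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise MissingColumnError(missing)


def _formula(outcome: str, extras, with_muscle: bool,
             interaction: bool = False) -> str:
    parts = [
        "age",
        "C(sex, Treatment('F'))",
        "C(disease, Treatment('control'))",
    ]
    if with_muscle:
        parts.append("C(muscle, Treatment('LG'))")
    if interaction:
        parts.append(
            "C(disease, Treatment('control')):C(muscle, Treatment('LG'))"
        )
    parts.extend(extras)
    return f"{outcome} ~ " + " + ".join(parts)


_TERM_RENAMES = {
    "Intercept": "Intercept",
    "C(sex, Treatment('F'))[T.M]": "sex_M",
    "C(disease, Treatment('control'))[T.FRDA]": "FRDA",
    "C(muscle, Treatment('LG'))[T.MG]": "muscle_MG",
    "C(muscle, Treatment('LG'))[T.Sol]": "muscle_Sol",
}


def _tidy_terms(params, ci, pvalues) -> pd.DataFrame:
    rows = []
    for name in params.index:
        rows.append(
            {
                "term": _TERM_RENAMES.get(name, name),
                "beta": float(params[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
                "p": float(pvalues[name]),
            }
        )
    return pd.DataFrame(rows)


def _tau_rows(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if outcome == "tau_s" and "status" in table.columns:
        return table[table["status"] == "ok"]
    return table


def fit_mixed_model(
    table: pd.DataFrame,
    outcome: str,
    model: str = "Model 1",
    reml: bool = True,
) -> ModelResult:
    """Random-intercept mixed model of one outcome across muscles.

    Fixed effects: age, sex, disease status, muscle (LG reference) plus
    the model's additional covariates; random intercept per subject;
    REML estimation; Wald-z confidence intervals.
    """
    if outcome not in MIXED_SUITES or model not in MIXED_SUITES[outcome]:
        raise ValueError(f"no declared mixed suite {model!r} for {outcome!r}")
    extras = MIXED_SUITES[outcome][model]
    _require_columns(table, BASE_COVARIATES + ["subject", "muscle", outcome]
                     + extras)
    data = _tau_rows(table, outcome)
    formula = _formula(outcome, extras, with_muscle=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, data, groups=data["subject"]).fit(reml=reml)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise SingularFitError(
                f"mixed model {model!r} for {outcome!r} is singular: {exc}"
            ) from exc
    fe = fit.fe_params
    bse = fit.bse_fe
    if not np.all(np.isfinite(bse)):
        raise SingularFitError(
            f"mixed model {model!r} for {outcome!r}: non-finite standard "
            "errors (singular fit)"
        )
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame(
        {0: fe - z * bse, 1: fe + z * bse}, index=fe.index
    )
    pvals = pd.Series(
        2 * stats.norm.sf(np.abs(fe / bse)), index=fe.index
    )
    terms = _tidy_terms(fe, ci, pvals)
    return ModelResult(
        outcome=outcome,
        model=model,
        terms=terms,
        n_subjects=data["subject"].nunique(),
        n_observations=len(data),
        kind="mixed",
        diagnostics={
            "converged": bool(fit.converged),
            "random_intercept_var": float(np.asarray(fit.cov_re)[0, 0]),
            "resid_var": float(fit.scale),
        },
    )


def detect_interaction(table: pd.DataFrame, outcome: str) -> float:
    """Likelihood-ratio p-value for a disease × muscle interaction.

    Fits the additive and interaction mixed models by maximum likelihood
    and refers twice the log-likelihood gap to χ² with (n_muscles − 1)
    degrees of freedom.
    """
    _require_columns(table, BASE_COVARIATES + ["subject", "muscle", outcome])
    data = _tau_rows(table, outcome)
    if data["muscle"].nunique() < 2:
        raise ValueError("interaction needs at least 2 muscle groups")
    if data["disease"].nunique() < 2:
        raise ValueError("interaction needs both disease groups")
    f0 = _formula(outcome, [], with_muscle=True)
    f1 = _formula(outcome, [], with_muscle=True, interaction=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            m0 = smf.mixedlm(f0, data, groups=data["subject"]).fit(reml=False)
            m1 = smf.mixedlm(f1, data, groups=data["subject"]).fit(reml=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise SingularFitError(str(exc)) from exc
    lr = 2.0 * (m1.llf - m0.llf)
    df = (data["muscle"].nunique() - 1) * (data["disease"].nunique() - 1)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def fit_linear_models_per_muscle(
    table: pd.DataFrame,
    outcome: str,
    models: list[str] | None = None,
) -> list[ModelResult]:
    """Per-muscle OLS suites fitted after an interaction was detected.

    Implausible τ rows (status ≠ ok) are dropped from τ models.  Raises
    :class:`RankDeficiencyError` when a model's design matrix is
    collinear.
    """
    if outcome not in OLS_SUITES:
        raise ValueError(f"no declared per-muscle suite for {outcome!r}")
    suite = OLS_SUITES[outcome]
    models = models or list(suite)
    results = []
    for muscle in MUSCLES:
        sub = table[table["muscle"] == muscle]
        sub = _tau_rows(sub, outcome)
        if not len(sub):
            continue
        for model in models:
            if model not in suite:
                raise ValueError(f"unknown model {model!r} for {outcome!r}")
            extras = suite[model]
            _require_columns(sub, BASE_COVARIATES + [outcome] + extras)
            formula = _formula(outcome, extras, with_muscle=False)
            mod = smf.ols(formula, sub)
            rank = np.linalg.matrix_rank(mod.exog)
            if rank < mod.exog.shape[1]:
                raise RankDeficiencyError(
                    f"design matrix for {outcome} {model} ({muscle}) is "
                    f"rank-deficient: rank {rank} < {mod.exog.shape[1]} columns"
                )
            fit = mod.fit()
            ci = fit.conf_int()
            terms = _tidy_terms(fit.params, ci, fit.pvalues)
            results.append(
                ModelResult(
                    outcome=outcome,
                    model=model,
                    terms=terms,
                    n_subjects=sub["subject"].nunique(),
                    n_observations=len(sub),
                    muscle=muscle,
                    kind="ols",
                    diagnostics={"rsquared": float(fit.rsquared)},
                )
            )
    return results


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile interval per (group, muscle, outcome).

    τ summaries use plausible (status ok) rows only.
    """
    rows = []
    for outc in OUTCOMES:
        if outc not in table.columns:
            continue
        data = _tau_rows(table, outc)
        for (disease, muscle), grp in data.groupby(
            ["disease", "muscle"], sort=False
        ):
            vals = grp[outc].dropna().to_numpy()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "outcome": outc,
                    "disease": disease,
                    "muscle": muscle,
                    "n": int(vals.size),
                    "median": float(np.median(vals)),
                    "iqi_low": float(np.percentile(vals, 25)),
                    "iqi_high": float(np.percentile(vals, 75)),
                }
            )
    return pd.DataFrame(rows)


class CohortModel:
    """Statsmodels-style front door to the cohort model suites.

    Holds the cohort table; ``fit_mixed`` / ``fit_per_muscle`` return
    :class:`ModelResult` objects, ``summary_table`` the median/IQI grid.
    """

    def __init__(self, table: pd.DataFrame):
        _require_columns(table, ["subject", "disease", "muscle"])
        self.table = table.copy()

    @classmethod
    def from_csv(cls, path) -> "CohortModel":
        return cls(pd.read_csv(path))

    def fit_mixed(self, outcome: str, model: str = "Model 1") -> ModelResult:
        return fit_mixed_model(self.table, outcome, model)

    def interaction_pvalue(self, outcome: str) -> float:
        return detect_interaction(self.table, outcome)

    def fit_per_muscle(self, outcome: str,
                       models: list[str] | None = None) -> list[ModelResult]:
        return fit_linear_models_per_muscle(self.table, outcome, models)

    def summary_table(self) -> pd.DataFrame:
        return summarize_cohort(self.table)
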