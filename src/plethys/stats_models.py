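"""Mixed-effects comparison designs for the phenotype metrics.

Three designs cover the assay structure:

* **pre/post** (room air, hypercapnia): linear mixed model
  ``value ~ group * cno`` with a per-animal random intercept, fit by REML;
  the reported term is the group x CNO interaction -- the
  difference-in-differences between experimental and control animals'
  pre-to-post change.
* **group-only** (hypoxia, temperature): one post-CNO value per animal, so
  the random intercept is not identifiable and the model reduces to a
  between-animal linear model; the reported term is experimental - control.
* **sex** variants add sex and its interactions to either design and report
  the sex-conditional contrast (the highest-order interaction with sex).

P-values use a between-within t reference: for within-animal terms the
denominator degrees of freedom are the number of animals minus the number
of between-animal cells, which makes the balanced-design interaction test
exact (it coincides with the two-sample t-test on per-animal change
scores).  The significance convention is p < 0.05 with no multiple-testing
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "fit_pre_post_model",
    "fit_group_model",
    "fit_sex_model",
    "pool_room_air",
    "effects_table",
    "significance_stars",
]

METRIC_COLUMNS = [
    "animal_id", "cross", "group", "sex", "cno_status", "condition", "metric", "value",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One fitted contrast: estimate, uncertainty and provenance."""

    metric: str
    term: str
    estimate: float
    se: float
    p_value: float
    df: float
    n_animals: int
    model: str
    condition: str | None = None
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("se must be >= 0")
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _check_long(data: pd.DataFrame, metric: str) -> pd.DataFrame:
    missing = [c for c in ("animal_id", "group", "cno_status", "metric", "value")
               if c not in data.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")
    sub = data[data["metric"] == metric].dropna(subset=["value"]).copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    if not np.isfinite(sub["value"]).all():
        raise ValueError("metric values must be finite")
    return sub


def _mixedlm_wald(
    endog: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    index: int,
    df: float,
) -> tuple[float, float, float, bool]:
    """Fit a random-intercept mixed model and return the Wald test of one
    coefficient against a t reference with the given df."""
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(endog, exog, groups=groups)
            fit = model.fit(reml=True)
            est = float(fit.fe_params[index])
            se = float(fit.bse_fe[index])
            converged = bool(getattr(fit, "converged", True))
        except (np.linalg.LinAlgError, ValueError):
            return np.nan, np.nan, np.nan, False
    if not np.isfinite(se) or se <= 0:
        return est, np.nan, np.nan, False
    p = 2.0 * sps.t.sf(abs(est / se), df)
    return est, se, float(p), converged


def fit_pre_post_model(data: pd.DataFrame, metric: str) -> EffectEstimate:
    """Group x CNO mixed model with a per-animal random intercept.

    Expects one value per animal x CNO status (pre and post) for a single
    condition; returns the interaction estimate (difference-in-differences,
    experimental relative to control)."""
    sub = _check_long(data, metric)
    conditions = sub["condition"].unique() if "condition" in sub else ["?"]
    if len(conditions) > 1:
        raise ValueError(f"pre/post model expects one condition, got {list(conditions)}")
    groups_present = set(sub["group"])
    if groups_present != {"experimental", "control"}:
        raise ValueError(f"both groups required, found {sorted(groups_present)}")
    if set(sub["cno_status"]) != {"pre", "post"}:
        raise ValueError("both pre and post CNO rows required")
    n_per = sub.groupby("group")["animal_id"].nunique()
    if (n_per < 2).any():
        raise ValueError("at least 2 animals per group required")

    g = (sub["group"] == "experimental").to_numpy(float)
    c = (sub["cno_status"] == "post").to_numpy(float)
    exog = np.column_stack([np.ones(len(sub)), g, c, g * c])
    n_animals = sub["animal_id"].nunique()
    df = max(n_animals - 2, 1)
    est, se, p, converged = _mixedlm_wald(
        sub["value"].to_numpy(), exog, sub["animal_id"].to_numpy(), index=3, df=df
    )
    return EffectEstimate(
        metric=metric,
        term="group:cno",
        estimate=est,
        se=se,
        p_value=p,
        df=df,
        n_animals=n_animals,
        model="MixedLM(REML), random intercept per animal, between-within df",
        condition=str(conditions[0]),
        converged=converged,
        note="" if converged else "non-convergence: result flagged",
    )


def fit_group_model(data: pd.DataFrame, metric: str) -> EffectEstimate:
    """Between-animal group comparison on post-CNO values.

    With a single value per animal the random intercept is not
    identifiable, so this is the mixed model's degenerate between-animal
    case: a linear model of group means, estimate = experimental - control.
    Multiple rows per animal (e.g. pooled assays) are averaged first."""
    sub = _check_long(data, metric)
    sub = sub[sub["cno_status"] == "post"]
    if sub.empty:
        raise ValueError("group-only model requires post-CNO rows")
    per_animal = sub.groupby(["animal_id", "group"], as_index=False)["value"].mean()
    groups_present = set(per_animal["group"])
    if groups_present != {"experimental", "control"}:
        raise ValueError(f"both groups required, found {sorted(groups_present)}")
    g = (per_animal["group"] == "experimental").to_numpy(float)
    y = per_animal["value"].to_numpy()
    n = len(per_animal)
    exog = np.column_stack([np.ones(n), g])
    fit = sm.OLS(y, exog).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    df = n - 2
    note = ""
    if min((g == 1).sum(), (g == 0).sum()) < 2:
        note = "low n: a group has a single animal; SE is unreliable"
    p = float(2.0 * sps.t.sf(abs(est / se), df)) if df > 0 and se > 0 else np.nan
    cond = sub["condition"].iloc[0] if "condition" in sub else None
    return EffectEstimate(
        metric=metric,
        term="group",
        estimate=est,
        se=se,
        p_value=p,
        df=max(df, 0),
        n_animals=n,
        model="between-animal linear model (degenerate mixed model)",
        condition=str(cond) if cond is not None else None,
        note=note,
    )


def fit_sex_model(data: pd.DataFrame, metric: str, design: str = "pre_post") -> EffectEstimate:
    """Add sex to a design and report the sex-conditional contrast.

    ``design='pre_post'``: value ~ group * cno * sex with a per-animal
    random intercept; the term is the group x cno x sex interaction (how
    the treatment effect differs in males relative to females).
    ``design='group_only'``: value ~ group * sex on post-CNO animal means;
    the term is group x sex.
    """
    if design not in ("pre_post", "group_only"):
        raise ValueError("design must be 'pre_post' or 'group_only'")
    sub = _check_long(data, metric)
    if "sex" not in sub.columns or set(sub["sex"]) != {"M", "F"}:
        raise ValueError("both sexes required for a sex model")
    if set(sub["group"]) != {"experimental", "control"}:
        raise ValueError("both groups required")

    if design == "group_only":
        sub = sub[sub["cno_status"] == "post"]
        per_animal = sub.groupby(["animal_id", "group", "sex"], as_index=False)["value"].mean()
        g = (per_animal["group"] == "experimental").to_numpy(float)
        s = (per_animal["sex"] == "M").to_numpy(float)
        exog = np.column_stack([np.ones(len(per_animal)), g, s, g * s])
        fit = sm.OLS(per_animal["value"].to_numpy(), exog).fit()
        df = len(per_animal) - 4
        est, se = float(fit.params[3]), float(fit.bse[3])
        p = float(2.0 * sps.t.sf(abs(est / se), df)) if df > 0 and se > 0 else np.nan
        return EffectEstimate(
            metric=metric, term="group:sex", estimate=est, se=se, p_value=p,
            df=max(df, 0), n_animals=len(per_animal),
            model="between-animal linear model with sex",
        )

    if set(sub["cno_status"]) != {"pre", "post"}:
        raise ValueError("both pre and post CNO rows required")
    g = (sub["group"] == "experimental").to_numpy(float)
    c = (sub["cno_status"] == "post").to_numpy(float)
    s = (sub["sex"] == "M").to_numpy(float)
    exog = np.column_stack(
        [np.ones(len(sub)), g, c, s, g * c, g * s, c * s, g * c * s]
    )
    n_animals = sub["animal_id"].nunique()
    df = max(n_animals - 4, 1)  # four between-animal cells: group x sex
    est, se, p, converged = _mixedlm_wald(
        sub["value"].to_numpy(), exog, sub["animal_id"].to_numpy(), index=7, df=df
    )
    return EffectEstimate(
        metric=metric, term="group:cno:sex", estimate=est, se=se, p_value=p,
        df=df, n_animals=n_animals,
        model="MixedLM(REML) with sex, random intercept per animal, between-within df",
        converged=converged,
        note="" if converged else "non-convergence: result flagged",
    )


def pool_room_air(
    hypercapnic_data: pd.DataFrame, hypoxic_data: pd.DataFrame
) -> pd.DataFrame:
    """Pool the room-air rows of the two assays, tagging provenance.

    Each animal is assayed once, so pooling enlarges the cohort.  Duplicate
    animal x assay x CNO x metric rows raise.  Statistical testing of an
    experimental cross should use only its sibling controls; pooled
    controls are for display tables."""
    frames = []
    for assay, frame in (("hypercapnic", hypercapnic_data), ("hypoxic", hypoxic_data)):
        sub = frame[frame["condition"] == "room_air"].copy()
        sub["assay"] = assay
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    keys = ["animal_id", "assay", "cno_status", "metric"]
    if pooled.duplicated(subset=keys).any():
        dup = pooled[pooled.duplicated(subset=keys, keep=False)]
        raise ValueError(
            f"duplicate animal x assay rows in room-air pool: "
            f"{dup[keys].drop_duplicates().to_dict('records')[:3]}"
        )
    return pooled


def significance_stars(p: float) -> str:
    """Figure convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def effects_table(effects: list[EffectEstimate]) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "metric": e.metric,
                "condition": e.condition,
                "term": e.term,
                "estimate": e.estimate,
                "se": e.se,
                "p_value": e.p_value,
                "stars": significance_stars(e.p_value),
                "df": e.df,
                "n_animals": e.n_animals,
                "model": e.model,
                "converged": e.converged,
                "note": e.note,
            }
        )
    return pd.DataFrame(rows)
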