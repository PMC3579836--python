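"""Forced-choice score encoding and the full statistical battery.

Scores live on the signed 8-point grid {-3.5, ..., +3.5}: the sign says
whether the correct match was chosen, the magnitude how strongly.  The
analysis mirrors the study design: per-participant one-sample t-tests
on the individual-discrimination (ID) trials, descriptive t-tests and
correlations, Gaussian mixed models with crossed random intercepts
(participant, triad, target/left/right image) fitted by maximum
likelihood, staged likelihood-ratio model reduction, and per-group
intercept estimation with parametric-bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import CrossedLMM, LMMFit, LRTResult, lrt, parametric_bootstrap

__all__ = [
    "SCORE_VALUES",
    "KD_FULL_TERMS",
    "ID_FULL_TERMS",
    "DEFAULT_RANDOM_FACTORS",
    "encode_score",
    "decode_score",
    "z_transform",
    "participant_id_screen",
    "summary_stats",
    "build_design",
    "fit_lmm",
    "lrt",
    "reduce_model",
    "ReductionResult",
]

SCORE_VALUES = (-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, 3.5)

#: treatment-coded fixed effects of the full kin-discrimination model
#: (reference levels: maternal, mixed-sex, inexperienced, female, left)
KD_FULL_TERMS = (
    "line",
    "triad_type",
    "experience",
    "trial_position_z",
    "participant_gender",
    "side_correct",
    "line:triad_type",
    "line:experience",
    "triad_type:experience",
    "trial_position_z:experience",
    "line:triad_type:experience",
)

ID_FULL_TERMS = (
    "triad_sex",
    "experience",
    "participant_gender",
    "trial_position_z",
    "side_correct",
    "triad_sex:experience",
    "trial_position_z:experience",
)

DEFAULT_RANDOM_FACTORS = (
    "participant",
    "triad_id",
    "target_image",
    "left_image",
    "right_image",
)


def encode_score(chosen_side: str, magnitude_step: int, correct_side: str) -> float:
    """Map a response to the signed grid: +/-(step - 0.5).

    ``magnitude_step`` runs 1 ("slightly more similar") to 4 ("much more
    similar"); the sign is positive iff the chosen side holds the
    correct match.
    """
    if magnitude_step not in (1, 2, 3, 4):
        raise ValueError("magnitude_step must be in 1..4")
    for side in (chosen_side, correct_side):
        if side not in ("left", "right"):
            raise ValueError("sides must be 'left' or 'right'")
    value = magnitude_step - 0.5
    return value if chosen_side == correct_side else -value

def decode_score(score: float) -> tuple[int, bool]:
    """Inverse of :func:`encode_score`: (magnitude_step, correct?)."""
    if score not in SCORE_VALUES:
        raise ValueError(f"{score} is not on the 8-point grid")
    return int(abs(score) + 0.5), score > 0


def z_transform(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to (sample, ddof=1) SD 1."""
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------------------
# per-participant screening and descriptives
# ---------------------------------------------------------------------------


def participant_id_screen(
    responses: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """One-sample t-test of each participant's 12 ID scores against 0.

    Returns the per-participant table and a summary with the number and
    fraction of participants whose mean differs significantly from
    chance.  Zero-variance participants are flagged (p undefined).
    """
    idt = responses[responses["kind"] == "ID"]
    if idt.empty:
        raise ValueError("no ID trials in the response table")
    rows = []
    for participant, grp in idt.groupby("participant"):
        scores = grp["score"].to_numpy(dtype=float)
        if len(scores) != 12:
            raise ValueError(
                f"participant {participant} has {len(scores)} ID trials, not 12"
            )
        if np.allclose(scores.std(ddof=1), 0.0):
            rows.append(
                {
                    "participant": participant,
                    "mean": scores.mean(),
                    "t": np.nan,
                    "df": 11,
                    "p": np.nan,
                    "significant": False,
                    "zero_variance": True,
                }
            )
            continue
        t, p = stats.ttest_1samp(scores, 0.0)
        rows.append(
            {
                "participant": participant,
                "mean": scores.mean(),
                "t": float(t),
                "df": 11,
                "p": float(p),
                "significant": bool(p < alpha),
                "zero_variance": False,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    n_sig = int(table["significant"].sum())
    return table, {
        "n_participants": n,
        "n_significant": n_sig,
        "fraction_significant": n_sig / n,
    }


def summary_stats(responses: pd.DataFrame) -> dict:
    """The descriptive battery on per-participant mean scores.

    Paired t-test of KD vs ID means, unpaired (pooled-variance) t-test
    of expert vs inexperienced KD means, Pearson correlation between ID
    and KD means, and Spearman rank correlations against experience
    duration when an ``experience_months`` column is present.
    """
    per = responses.pivot_table(
        index="participant", columns="kind", values="score", aggfunc="mean"
    )
    if len(per) < 3:
        raise ValueError("need at least 3 participants")
    kd, idm = per["KD"].to_numpy(), per["ID"].to_numpy()
    if np.allclose(kd - idm, (kd - idm)[0]):
        # zero-variance differences: t is 0 when means agree, undefined
        # otherwise; scipy would return nan for both
        t_paired = 0.0 if np.allclose(kd, idm) else np.nan
        p_paired = 1.0 if t_paired == 0.0 else np.nan
    else:
        t_paired, p_paired = stats.ttest_rel(kd, idm)
    exp_map = responses.groupby("participant")["experience"].first()
    expert_mask = (exp_map.loc[per.index] == "expert").to_numpy()
    out = {
        "kd_mean_sd": (float(kd.mean()), float(kd.std(ddof=1))),
        "id_mean_sd": (float(idm.mean()), float(idm.std(ddof=1))),
        "paired_t_kd_vs_id": {
            "t": float(t_paired),
            "df": len(per) - 1,
            "p": float(p_paired),
        },
        "pearson_id_kd": None,
        "unpaired_t_experience": None,
    }
    if np.std(idm) > 0 and np.std(kd) > 0:
        r, p = stats.pearsonr(idm, kd)
        out["pearson_id_kd"] = {"r": float(r), "n": len(per), "p": float(p)}
    else:
        out["pearson_id_kd"] = {"r": float("nan"), "n": len(per), "p": float("nan")}
    if 0 < expert_mask.sum() < len(per):
        t_u, p_u = stats.ttest_ind(kd[expert_mask], kd[~expert_mask], equal_var=True)
        out["unpaired_t_experience"] = {
            "t": float(t_u),
            "df": len(per) - 2,
            "p": float(p_u),
            "expert_mean_sd": (
                float(kd[expert_mask].mean()),
                float(kd[expert_mask].std(ddof=1)),
            ),
            "inexperienced_mean_sd": (
                float(kd[~expert_mask].mean()),
                float(kd[~expert_mask].std(ddof=1)),
            ),
        }
    if "experience_months" in responses.columns:
        months = responses.groupby("participant")["experience_months"].first()
        months = months.loc[per.index].to_numpy(dtype=float)
        rs_id, p_id = stats.spearmanr(months, idm)
        rs_kd, p_kd = stats.spearmanr(months, kd)
        out["spearman_months_id"] = {"r": float(rs_id), "p": float(p_id)}
        out["spearman_months_kd"] = {"r": float(rs_kd), "p": float(p_kd)}
    return out


# ---------------------------------------------------------------------------
# design matrices and model fitting
# ---------------------------------------------------------------------------

_MAIN_CODES = {
    "line": ("line", "paternal"),
    "triad_type": ("triad_type", "same"),
    "experience": ("experience", "expert"),
    "participant_gender": ("participant_gender", "M"),
    "side_correct": ("side_correct", "right"),
    "triad_sex": ("triad_sex", "male"),
}


def _main_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "trial_position_z":
        if "trial_position_z" in df.columns:
            return df["trial_position_z"].to_numpy(dtype=float)
        return z_transform(df["trial_position"].to_numpy(dtype=float))
    column, level = _MAIN_CODES[term]
    return (df[column] == level).to_numpy(dtype=float)


def build_design(
    df: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effect matrix with a leading intercept."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in terms:
        parts = term.split(":")
        col = _main_column(df, parts[0])
        for part in parts[1:]:
            col = col * _main_column(df, part)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


def fit_lmm(
    responses: pd.DataFrame,
    fixed_terms: Sequence[str],
    random_factors: Sequence[str] = DEFAULT_RANDOM_FACTORS,
    random_slope: tuple[str, bool] | None = None,
    starts: Sequence[np.ndarray] | None = None,
) -> LMMFit:
    """ML fit of the Gaussian mixed model on a response table.

    ``random_slope=(factor, correlated)`` adds a per-level random slope
    on the z-transformed trial position, optionally with an
    intercept-slope correlation.
    """
    X, names = build_design(responses, fixed_terms)
    y = responses["score"].to_numpy(dtype=float)
    factors = []
    for factor in random_factors:
        codes, _ = pd.factorize(responses[factor])
        factors.append((factor, codes))
    slope = None
    if random_slope is not None:
        factor, correlated = random_slope
        covariate = _main_column(responses, "trial_position_z")
        slope = (factor, covariate, correlated)
    model = CrossedLMM(X, y, factors, fe_names=names, slope=slope)
    return model.fit(starts=starts)


# ---------------------------------------------------------------------------
# staged model reduction
# ---------------------------------------------------------------------------


@dataclass
class ReductionResult:
    """Trace and outcome of the staged model-reduction procedure."""

    random_structure: str
    random_tests: list[dict] = field(default_factory=list)
    overall_test: LRTResult | None = None
    trace: list[dict] = field(default_factory=list)
    final_terms: list[str] = field(default_factory=list)
    final_fit: LMMFit | None = None
    term_tests: dict[str, LRTResult] = field(default_factory=dict)
    group_intercepts: dict[str, dict] = field(default_factory=dict)


def _contains(container: str, term: str) -> bool:
    cset, tset = set(container.split(":")), set(term.split(":"))
    return tset < cset


def _deletion_test(
    responses: pd.DataFrame,
    terms: list[str],
    term: str,
    random_factors: Sequence[str],
    random_slope: tuple[str, bool] | None,
    cache: dict,
) -> tuple[LRTResult, LMMFit]:
    key = tuple(terms)
    if key not in cache:
        cache[key] = fit_lmm(responses, terms, random_factors, random_slope)
    full = cache[key]
    reduced_terms = [t for t in terms if t != term]
    rkey = tuple(reduced_terms)
    if rkey not in cache:
        # warm-start the reduced fit at the full model's variance parameters
        starts = [full.theta] + full.model.default_starts()[:1]
        cache[rkey] = fit_lmm(
            responses, reduced_terms, random_factors, random_slope, starts=starts
        )
    return lrt(full, cache[rkey]), full


def reduce_model(
    responses: pd.DataFrame,
    full_terms: Sequence[str] = KD_FULL_TERMS,
    random_factors: Sequence[str] = DEFAULT_RANDOM_FACTORS,
    test_random_slope: bool = True,
    slope_factor: str = "participant",
    primary_terms: Sequence[str] = ("line", "triad_type", "experience"),
    control_terms: Sequence[str] = ("participant_gender", "side_correct"),
    group_factor: str | None = "experience",
    alpha: float = 0.05,
    trend: float = 0.10,
    n_boot: int = 1000,
    seed: int = 0,
) -> ReductionResult:
    """The staged reduction procedure on one response table.

    1. Test the random intercept-slope correlation, then the random
       slope itself, by likelihood-ratio tests (df = 1 each).
    2. Establish overall significance of the full fixed model against a
       null retaining only the control variables.
    3. Drop nonsignificant interactions (highest order first), then
       nonsignificant control main effects; terms showing nonsignificant
       trends (p < ``trend``) are retained, as are the primary effects.
    4. Re-run with all nonsignificant fixed effects excluded to estimate
       the intercept; if ``group_factor`` is significant this is done
       separately per level, keeping whichever within-group covariates
       stay significant.  Intercepts get parametric-bootstrap intervals.

    Everything is deterministic given the data and ``seed``.
    """
    full_terms = list(full_terms)
    result = ReductionResult(random_structure="intercepts")
    cache: dict = {}

    # stage 1: random-effects structure
    random_slope = None
    if test_random_slope:
        fit_corr = fit_lmm(responses, full_terms, random_factors, (slope_factor, True))
        fit_slope = fit_lmm(responses, full_terms, random_factors, (slope_factor, False))
        fit_int = fit_lmm(responses, full_terms, random_factors, None)
        test_corr = lrt(fit_corr, fit_slope)
        result.random_tests.append(
            {"test": "intercept-slope correlation", **vars(test_corr)}
        )
        if test_corr.p < alpha:
            random_slope = (slope_factor, True)
            result.random_structure = "intercepts + correlated slope"
        else:
            test_slope = lrt(fit_slope, fit_int)
            result.random_tests.append(
                {"test": "random slope", **vars(test_slope)}
            )
            if test_slope.p < alpha:
                random_slope = (slope_factor, False)
                result.random_structure = "intercepts + slope"
    current = list(full_terms)
    cache[tuple(current)] = fit_lmm(responses, current, random_factors, random_slope)

    # stage 2: overall significance of the full model
    null_terms = [t for t in control_terms if t in current]
    null_fit = fit_lmm(responses, null_terms, random_factors, random_slope)
    result.overall_test = lrt(cache[tuple(current)], null_fit)

    # stage 3: backward elimination respecting marginality
    while True:
        droppable = [
            t
            for t in current
            if not any(_contains(other, t) for other in current)
            and (":" in t or t in control_terms)
        ]
        tests = {}
        for term in droppable:
            tests[term], current_fit = _deletion_test(
                responses, current, term, random_factors, random_slope, cache
            )
        if not tests:
            break
        worst = max(tests, key=lambda t: tests[t].p)
        test = tests[worst]
        if test.p < trend:
            break
        current_fit = cache[tuple(current)]
        result.trace.append(
            {
                "term": worst,
                "estimate": float(current_fit.beta[worst]),
                "chi_sq": test.chi_sq,
                "df": test.df,
                "p": test.p,
                "action": "dropped",
            }
        )
        current = [t for t in current if t != worst]

    result.final_terms = list(current)
    result.final_fit = cache.get(tuple(current)) or fit_lmm(
        responses, current, random_factors, random_slope
    )
    for term in current:
        test, _ = _deletion_test(
            responses, current, term, random_factors, random_slope, cache
        )
        result.term_tests[term] = test

    # stage 4: intercept estimation (per significant group level)
    boot_seed = seed
    grouped = (
        group_factor is not None
        and group_factor in result.term_tests
        and result.term_tests[group_factor].p < alpha
    )
    if grouped:
        column, _ = _MAIN_CODES[group_factor]
        levels = {
            str(value): responses[column] == value
            for value in sorted(responses[column].unique())
        }
        for level, mask in levels.items():
            sub = responses[mask]
            candidates = sorted(
                {
                    ":".join(p for p in t.split(":") if p != group_factor)
                    for t in current
                    if t != group_factor
                }
                - {""}
            )
            kept = list(candidates)
            sub_cache: dict = {}
            changed = True
            while changed and kept:
                changed = False
                tests = {}
                for term in kept:
                    tests[term], _ = _deletion_test(
                        sub, kept, term, random_factors, None, sub_cache
                    )
                worst = max(tests, key=lambda t: tests[t].p)
                if tests[worst].p >= alpha:
                    kept = [t for t in kept if t != worst]
                    changed = True
            fit = fit_lmm(sub, kept, random_factors, None)
            boot = parametric_bootstrap(fit, n_boot=n_boot, seed=boot_seed)
            boot_seed += 1
            result.group_intercepts[level] = {
                "terms": kept,
                "fit": fit,
                "intercept": float(fit.beta["intercept"]),
                "lower": float(boot.loc["intercept", "lower"]),
                "upper": float(boot.loc["intercept", "upper"]),
                "p": float(boot.loc["intercept", "p"]),
            }
    else:
        kept = [t for t in current if result.term_tests[t].p < alpha]
        fit = fit_lmm(responses, kept, random_factors, random_slope)
        boot = parametric_bootstrap(fit, n_boot=n_boot, seed=boot_seed)
        result.group_intercepts["all"] = {
            "terms": kept,
            "fit": fit,
            "intercept": float(fit.beta["intercept"]),
            "lower": float(boot.loc["intercept", "lower"]),
            "upper": float(boot.loc["intercept", "upper"]),
            "p": float(boot.loc["intercept", "p"]),
        }
    return result
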