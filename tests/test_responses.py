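"""Score encoding, response simulation and the statistical battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinface import ResponseSimConfig, simulate_responses
from kinface import responses as rs
from kinface.simulate import SCORE_GRID, discretize_score


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def test_encode_score_examples():
    assert rs.encode_score("left", 4, "left") == 3.5    # outermost, correct
    assert rs.encode_score("left", 4, "right") == -3.5  # outermost, wrong
    assert rs.encode_score("right", 1, "right") == 0.5  # innermost, correct
    with pytest.raises(ValueError):
        rs.encode_score("left", 5, "left")
    with pytest.raises(ValueError):
        rs.encode_score("up", 2, "left")


def test_score_round_trip():
    for score in rs.SCORE_VALUES:
        step, correct = rs.decode_score(score)
        chosen = "left" if correct else "right"
        assert rs.encode_score(chosen, step, "left") == score


def test_z_transform_invariant():
    rng = np.random.default_rng(0)
    x = rng.normal(3, 7, size=44)
    z = rs.z_transform(x)
    assert abs(z.mean()) < 1e-12
    assert abs(z.std(ddof=1) - 1) < 1e-12


# ---------------------------------------------------------------------------
# response generator
# ---------------------------------------------------------------------------


def _null_config(**kwargs):
    beta = {k: 0.0 for k in (
        "intercept", "line", "triad_type", "experience", "trial_position",
        "line_x_experience", "trial_position_x_experience", "id_intercept",
        "triad_sex",
    )}
    defaults = dict(
        n_participants=4, beta=beta,
        sigma_participant=0.0, sigma_triad=0.0, sigma_target=0.0,
        sigma_left=0.0, sigma_right=0.0, sigma_resid=0.0, seed=3,
    )
    defaults.update(kwargs)
    return ResponseSimConfig(**defaults)


def test_all_zero_gives_tie_break_score(kd_triads, id_triads, schedules):
    """Betas and sigmas all zero: every latent is 0, which the tie rule
    maps to +0.5."""
    resp = simulate_responses(kd_triads + id_triads, schedules, _null_config())
    assert (resp["score"] == 0.5).all()


def test_large_intercept_clamps_to_grid_end(kd_triads, id_triads, schedules):
    config = _null_config()
    config.beta["intercept"] = 10.0
    config.beta["id_intercept"] = 10.0
    resp = simulate_responses(kd_triads + id_triads, schedules, config)
    assert (resp["score"] == 3.5).all()


def test_sign_symmetry_of_fixed_effects(kd_triads, id_triads, schedules):
    """With zero random noise, negating every beta negates the latent
    scores trial for trial."""
    base = ResponseSimConfig(
        sigma_participant=0.0, sigma_triad=0.0, sigma_target=0.0,
        sigma_left=0.0, sigma_right=0.0, sigma_resid=0.0, seed=5,
    )
    flipped = ResponseSimConfig(
        beta={k: -v for k, v in base.beta.items()},
        sigma_participant=0.0, sigma_triad=0.0, sigma_target=0.0,
        sigma_left=0.0, sigma_right=0.0, sigma_resid=0.0, seed=5,
    )
    a = simulate_responses(kd_triads + id_triads, schedules, base)
    b = simulate_responses(kd_triads + id_triads, schedules, flipped)
    assert np.allclose(a["latent"].to_numpy(), -b["latent"].to_numpy())


def test_scores_lie_on_grid(responses_df):
    assert responses_df["score"].isin(rs.SCORE_VALUES).all()


def test_discretize_grid_and_ties():
    latent = np.array([0.0, 0.2, -0.2, 1.0, 5.0, -9.0, 3.49])
    out = discretize_score(latent)
    assert out.tolist() == [0.5, 0.5, -0.5, 1.5, 3.5, -3.5, 3.5]
    assert np.isin(out, SCORE_GRID).all()


# ---------------------------------------------------------------------------
# per-participant screening and descriptives
# ---------------------------------------------------------------------------


def test_participant_screen_zero_variance_flagged(responses_df):
    forced = responses_df.copy()
    p0 = forced["participant"].iloc[0]
    forced.loc[(forced["participant"] == p0) & (forced["kind"] == "ID"), "score"] = 3.5
    table, summary = rs.participant_id_screen(forced)
    row = table[table["participant"] == p0].iloc[0]
    assert row["zero_variance"] and not row["significant"]
    assert np.isnan(row["p"])


def test_participant_screen_symmetric_scores_not_significant(responses_df):
    forced = responses_df.copy()
    p0 = forced["participant"].iloc[0]
    mask = (forced["participant"] == p0) & (forced["kind"] == "ID")
    forced.loc[mask, "score"] = [0.5, -0.5] * 6  # mean exactly 0
    table, _ = rs.participant_id_screen(forced)
    row = table[table["participant"] == p0].iloc[0]
    assert row["mean"] == 0.0
    assert not row["significant"]


def test_summary_stats_hand_computed_two_groups():
    """Unpaired t on a constructed two-group fixture equals the textbook
    pooled-variance formula."""
    rows = []
    kd_means = {"expert": [1.0, 0.8, 0.9], "inexperienced": [0.4, 0.5, 0.6]}
    p = 0
    for group, means in kd_means.items():
        for mu in means:
            p += 1
            for k in range(2):
                rows.append(
                    {
                        "participant": f"P{p}",
                        "kind": "KD",
                        "score": mu,
                        "experience": group,
                    }
                )
            rows.append(
                {
                    "participant": f"P{p}",
                    "kind": "ID",
                    "score": 2.0,
                    "experience": group,
                }
            )
    df = pd.DataFrame(rows)
    out = rs.summary_stats(df)
    a = np.array(kd_means["expert"])
    b = np.array(kd_means["inexperienced"])
    sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 /= len(a) + len(b) - 2
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    assert out["unpaired_t_experience"]["t"] == pytest.approx(t_hand)
    assert out["unpaired_t_experience"]["df"] == 4
    # identical KD and ID per-participant means give paired t = 0
    df_equal = df.copy()
    df_equal.loc[df_equal["kind"] == "ID", "score"] = np.repeat(
        [1.0, 0.8, 0.9, 0.4, 0.5, 0.6], 1
    )
    out_equal = rs.summary_stats(df_equal)
    assert out_equal["paired_t_kd_vs_id"]["t"] == pytest.approx(0.0, abs=1e-12)


def test_summary_stats_needs_three_participants():
    df = pd.DataFrame(
        {
            "participant": ["a", "a", "b", "b"],
            "kind": ["KD", "ID"] * 2,
            "score": [1, 2, 3, 4],
            "experience": ["expert"] * 4,
        }
    )
    with pytest.raises(ValueError):
        rs.summary_stats(df)


def test_unpaired_t_calibrated_under_label_permutation():
    """Permuting experience labels gives a rejection rate near alpha."""
    rng = np.random.default_rng(11)
    means = rng.normal(0.6, 0.3, size=40)
    rejections = 0
    n_perm = 400
    for _ in range(n_perm):
        labels = rng.permutation([True] * 20 + [False] * 20)
        t, p = stats.ttest_ind(means[labels], means[~labels], equal_var=True)
        rejections += p < 0.05
    rate = rejections / n_perm
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_perm) + 0.01


# ---------------------------------------------------------------------------
# design matrices and reduction
# ---------------------------------------------------------------------------


def test_build_design_treatment_coding(responses_df):
    kd = responses_df[responses_df["kind"] == "KD"].head(200)
    X, names = rs.build_design(
        kd, ["line", "experience", "line:experience", "trial_position_z"]
    )
    assert names[0] == "intercept" and (X[:, 0] == 1).all()
    line = (kd["line"] == "paternal").to_numpy(float)
    exp = (kd["experience"] == "expert").to_numpy(float)
    assert np.array_equal(X[:, 1], line)
    assert np.array_equal(X[:, 3], line * exp)
    assert np.allclose(X[:, 4], kd["trial_position_z"])


def test_reduction_intercept_only_data(kd_triads, id_triads):
    """Pure-intercept data: the trace drops every interaction and control
    and the final per-group refit is intercept-only."""
    from kinface import triads as tr

    sched = {
        f"P{i:03d}": tr.randomize_session(kd_triads, id_triads, f"P{i:03d}", 500 + i)
        for i in range(24)
    }
    beta = {k: 0.0 for k in ResponseSimConfig().beta}
    beta["intercept"] = 0.9
    config = ResponseSimConfig(
        n_participants=24, beta=beta, sigma_participant=0.1,
        sigma_triad=0.1, sigma_target=0.05, sigma_left=0.05,
        sigma_right=0.05, sigma_resid=1.2, seed=21,
    )
    resp = simulate_responses(kd_triads + id_triads, sched, config)
    kd_data = resp[resp["kind"] == "KD"]
    result = rs.reduce_model(kd_data, n_boot=60, seed=0)
    assert result.random_structure == "intercepts"
    dropped = {d["term"] for d in result.trace}
    assert "line:triad_type:experience" in dropped
    assert result.overall_test is not None
    # no genuine effects: the grouped path is not triggered and the final
    # intercept-only refit recovers the generating intercept
    assert list(result.group_intercepts) == ["all"]
    info = result.group_intercepts["all"]
    assert info["terms"] == []
    assert info["intercept"] == pytest.approx(0.9, abs=0.25)
    assert info["p"] < 0.05


def test_reduction_recovers_experience_by_position_interaction(
    kd_triads, id_triads
):
    """Data generated with an experience-dependent practice effect keep the
    trial_position x experience interaction, and the per-group refits show
    a positive slope only in the inexperienced group."""
    from kinface import triads as tr

    sched = {
        f"P{i:03d}": tr.randomize_session(kd_triads, id_triads, f"P{i:03d}", 900 + i)
        for i in range(48)
    }
    beta = {k: 0.0 for k in ResponseSimConfig().beta}
    beta.update(
        intercept=0.45, experience=0.35,
        trial_position=0.30, trial_position_x_experience=-0.30,
    )
    config = ResponseSimConfig(
        n_participants=48, p_expert=0.5, beta=beta,
        sigma_participant=0.2, sigma_triad=0.1, sigma_target=0.05,
        sigma_left=0.05, sigma_right=0.05, sigma_resid=1.0, seed=22,
    )
    resp = simulate_responses(kd_triads + id_triads, sched, config)
    kd_data = resp[resp["kind"] == "KD"]
    result = rs.reduce_model(kd_data, n_boot=60, seed=0)
    assert "trial_position_z:experience" in result.final_terms
    assert result.term_tests["experience"].p < 0.05
    groups = result.group_intercepts
    assert set(groups) == {"expert", "inexperienced"}
    assert "trial_position_z" in groups["inexperienced"]["terms"]
    inexp_fit = groups["inexperienced"]["fit"]
    assert inexp_fit.beta.get("trial_position_z", 0.0) > 0.1
    expert_terms = groups["expert"]["terms"]
    assert "trial_position_z" not in expert_terms
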