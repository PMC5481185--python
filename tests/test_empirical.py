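"""Tests for the empirical epistasis-estimation pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epicre
from epicre.empirical import (
    ENV_NO_REPRESSOR,
    ENV_REPRESSOR,
    EpistasisClass,
    classify_type,
    classify_types,
    conformity_test,
    environment_comparison,
    estimate_epistasis,
    gxgxe_test,
    normalize,
    predict_signs_from_singles,
    sign_bias_test,
)
from epicre.thermo import EpistasisSign


def make_fluor(means, reps=6, noise_sd=0.0, seed=0, env=ENV_NO_REPRESSOR, blank=0.0):
    """Tidy fluorescence table from genotype -> mean, optional lognormal noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for gid, mean in {**means, "blank": blank}.items():
        noise = np.exp(rng.normal(0, noise_sd, reps)) if noise_sd else np.ones(reps)
        for k, v in enumerate(mean * noise):
            rows.append((gid, env, k + 1, float(v)))
    return pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "fluorescence"])


PAIRS = pd.DataFrame([{"double": "d", "single1": "m1", "single2": "m2"}])


# ---------------------------------------------------------------------------
# normalize

def test_normalize_wildtype_is_one():
    norm = normalize(make_fluor({"WT": 3.0, "m1": 6.0}))
    assert norm.loc[("WT", ENV_NO_REPRESSOR), "f"] == pytest.approx(1.0)
    assert norm.loc[("m1", ENV_NO_REPRESSOR), "f"] == pytest.approx(2.0)


def test_normalize_blank_correction():
    norm = normalize(make_fluor({"WT": 1.2, "m1": 0.7}, blank=0.2))
    assert norm.loc[("m1", ENV_NO_REPRESSOR), "f"] == pytest.approx(0.5)


def test_normalize_zero_variance_gives_zero_sd():
    norm = normalize(make_fluor({"WT": 1.0, "m1": 0.5}))
    assert norm.loc[("m1", ENV_NO_REPRESSOR), "f_sd"] == pytest.approx(0.0)
    assert norm.loc[("m1", ENV_NO_REPRESSOR), "relvar"] == pytest.approx(0.0)


def test_normalize_rejects_wildtype_below_blank():
    with pytest.raises(ValueError):
        normalize(make_fluor({"WT": 0.1, "m1": 0.5}, blank=0.2))


def test_normalize_floors_nonpositive_with_warning():
    fluor = make_fluor({"WT": 1.2, "m1": 0.1}, blank=0.2)
    with pytest.warns(UserWarning, match="floored"):
        norm = normalize(fluor)
    row = norm.loc[("m1", ENV_NO_REPRESSOR)]
    assert bool(row["floored"])
    assert row["f"] == pytest.approx(1e-4)


def test_normalize_requires_two_replicates():
    fluor = make_fluor({"WT": 1.0, "m1": 0.5}, reps=1)
    with pytest.raises(ValueError, match="replicates"):
        normalize(fluor)


def test_normalize_requires_wildtype():
    with pytest.raises(ValueError, match="wildtype"):
        normalize(make_fluor({"m1": 0.5}))


def test_normalize_rejects_negative_fluorescence():
    fluor = make_fluor({"WT": 1.0, "m1": 0.5})
    fluor.loc[0, "fluorescence"] = -0.1
    with pytest.raises(ValueError):
        normalize(fluor)


# ---------------------------------------------------------------------------
# estimate_epistasis

def test_estimate_exact_multiplicativity():
    norm = normalize(make_fluor({"WT": 1.0, "m1": 0.5, "m2": 0.5, "d": 0.25}))
    est = estimate_epistasis(norm, PAIRS)
    assert est.loc[0, "epsilon"] == pytest.approx(1.0)


def test_estimate_hand_value():
    norm = normalize(make_fluor({"WT": 1.0, "m1": 0.5, "m2": 0.5, "d": 0.1}))
    est = estimate_epistasis(norm, PAIRS)
    assert est.loc[0, "epsilon"] == pytest.approx(0.4)
    assert est.loc[0, "log_epsilon"] < 0


def test_estimate_scale_invariance():
    base = make_fluor({"WT": 1.0, "m1": 0.4, "m2": 0.7, "d": 0.2}, noise_sd=0.1, seed=4)
    scaled = base.copy()
    scaled["fluorescence"] *= 137.0
    e1 = estimate_epistasis(normalize(base), PAIRS)
    e2 = estimate_epistasis(normalize(scaled), PAIRS)
    assert e1.loc[0, "epsilon"] == pytest.approx(e2.loc[0, "epsilon"], rel=1e-12)
    assert e1.loc[0, "t"] == pytest.approx(e2.loc[0, "t"], rel=1e-12)


def test_estimate_df_is_replicates_minus_one():
    norm = normalize(make_fluor({"WT": 1.0, "m1": 0.5, "m2": 0.5, "d": 0.1}, reps=6))
    est = estimate_epistasis(norm, PAIRS)
    assert int(est.loc[0, "df"]) == 5


def test_estimate_sign_none_iff_not_significant(default_estimates):
    _, est = default_estimates
    not_sig = est[~est["significant"]]
    sig = est[est["significant"]]
    assert (not_sig["sign"] == "none").all()
    assert (sig["sign"] != "none").all()


def test_estimate_q_monotone_in_p(default_estimates):
    _, est = default_estimates
    for _, sub in est.groupby("environment"):
        s = sub.sort_values("p")
        assert (np.diff(s["q"].to_numpy()) >= -1e-12).all()


def test_estimate_missing_genotype_raises():
    norm = normalize(make_fluor({"WT": 1.0, "m1": 0.5, "d": 0.1}))
    with pytest.raises(ValueError, match="missing"):
        estimate_epistasis(norm, PAIRS)


# ---------------------------------------------------------------------------
# classify_type

def test_classify_reciprocal_sign():
    cls, caveat = classify_type(0.5, 0.5, 1.5, significant=True)
    assert cls is EpistasisClass.RECIPROCAL_SIGN
    assert caveat is False


def test_classify_negative_magnitude():
    cls, _ = classify_type(0.5, 0.5, 0.1, significant=True)
    assert cls is EpistasisClass.NEGATIVE_MAGNITUDE


def test_classify_positive_magnitude():
    cls, _ = classify_type(0.5, 0.5, 0.4, significant=True)  # eps = 1.6, no flips
    assert cls is EpistasisClass.POSITIVE_MAGNITUDE


def test_classify_single_flip_is_sign():
    # m1 deleterious alone but beneficial on m2's background; m2 never flips
    cls, _ = classify_type(0.5, 1.5, 2.0, significant=True)
    assert cls is EpistasisClass.SIGN


def test_classify_not_significant_with_caveat():
    cls, caveat = classify_type(0.5, 0.5, 1.5, significant=False)
    assert cls is EpistasisClass.NO_EPISTASIS
    assert caveat is True


def test_classify_neutral_single_cannot_flip():
    cls, _ = classify_type(1.0, 0.5, 0.4, significant=True)
    assert cls in (EpistasisClass.POSITIVE_MAGNITUDE, EpistasisClass.NEGATIVE_MAGNITUDE)


def test_classify_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_type(0.0, 0.5, 0.5)


def test_classify_types_adds_columns(default_estimates):
    _, est = default_estimates
    out = classify_types(est)
    assert {"epistasis_class", "flip_without_significance"} <= set(out.columns)
    assert (out.loc[~out["significant"], "epistasis_class"] == "no_epistasis").all()


# ---------------------------------------------------------------------------
# environment comparison

def two_env_estimates(eps_a, eps_b, sig_a=True, sig_b=True):
    rows = []
    for env, eps, sig in ((ENV_NO_REPRESSOR, eps_a, sig_a), (ENV_REPRESSOR, eps_b, sig_b)):
        rows.append(
            {
                "double": "d",
                "environment": env,
                "log_epsilon": np.log(eps),
                "significant": sig,
                "sign": ("none" if not sig else ("positive" if eps > 1 else "negative")),
            }
        )
    return pd.DataFrame(rows)


def test_environment_comparison_changed():
    per, summary = environment_comparison(two_env_estimates(0.5, 2.0))
    assert per.loc["d", "changed"] == "yes"
    assert summary["n_changed"] == 1
    assert per.loc["d", "delta_log10"] == pytest.approx(np.log10(4.0))


def test_environment_comparison_unchanged():
    per, summary = environment_comparison(two_env_estimates(0.5, 0.5))
    assert per.loc["d", "changed"] == "no"
    assert summary["n_always_negative"] == 1


def test_environment_comparison_indeterminate_strict_lenient():
    est = two_env_estimates(0.5, 2.0, sig_a=False)
    per_strict, s_strict = environment_comparison(est, lenient=False)
    assert per_strict.loc["d", "changed"] == "indeterminate"
    assert s_strict["n_changed"] == 0
    per_len, s_len = environment_comparison(est, lenient=True)
    assert per_len.loc["d", "changed"] == "yes"
    assert s_len["n_changed"] == 1


def test_environment_comparison_warns_on_missing_environment():
    est = two_env_estimates(0.5, 2.0)
    extra = est.iloc[[0]].assign(double="lonely")
    with pytest.warns(UserWarning, match="lack an estimate"):
        per, _ = environment_comparison(pd.concat([est, extra], ignore_index=True))
    assert "lonely" not in per.index


# ---------------------------------------------------------------------------
# cohort statistics

def sig_frame(n_pos, n_neg):
    rows = [
        {"double": f"p{i}", "environment": ENV_NO_REPRESSOR, "significant": True,
         "sign": "positive", "log_epsilon": 0.5}
        for i in range(n_pos)
    ] + [
        {"double": f"n{i}", "environment": ENV_NO_REPRESSOR, "significant": True,
         "sign": "negative", "log_epsilon": -0.5}
        for i in range(n_neg)
    ]
    return pd.DataFrame(rows)


def test_sign_bias_balanced_is_zero():
    res = sign_bias_test(sig_frame(10, 10))
    assert res.chi2 == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_sign_bias_hand_value():
    res = sign_bias_test(sig_frame(94, 19))
    assert res.chi2 == pytest.approx(2 * 37.5**2 / 56.5, rel=1e-12)
    assert res.chi2 == pytest.approx(49.78, abs=0.01)
    assert res.n_positive == 94 and res.n_negative == 19


def test_sign_bias_one_sided_counts():
    res = sign_bias_test(sig_frame(12, 0))
    assert res.chi2 == pytest.approx(12.0)


def test_sign_bias_requires_significant():
    empty = sig_frame(1, 0)
    empty["significant"] = False
    with pytest.raises(ValueError):
        sign_bias_test(empty)


def test_gxgxe_identical_deviations():
    # per-pair deviations vary, but identically in the two environments
    est = pd.concat(
        [two_env_estimates(0.4 + 0.1 * i, 0.4 + 0.1 * i).assign(double=f"d{i}") for i in range(5)],
        ignore_index=True,
    )
    res = gxgxe_test(est)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.df_num == 1 and res.df_den == 8


def test_gxgxe_detects_environment_dependence(default_estimates):
    _, est = default_estimates
    res = gxgxe_test(est)
    assert res.df_den == 2 * 141 - 2
    assert res.p < 0.01


def test_gxgxe_permutation_null_uniform(default_estimates):
    _, est = default_estimates
    sub = est[["double", "environment", "log_epsilon"]].copy()
    rng = np.random.default_rng(17)
    pvals = []
    for _ in range(300):
        shuffled = sub.copy()
        # permute environment labels within each double mutant
        flip = rng.random(sub["double"].nunique()) < 0.5
        flip_map = dict(zip(sub["double"].unique(), flip))
        swap = shuffled["double"].map(flip_map)
        shuffled.loc[swap, "environment"] = shuffled.loc[swap, "environment"].map(
            {ENV_NO_REPRESSOR: ENV_REPRESSOR, ENV_REPRESSOR: ENV_NO_REPRESSOR}
        )
        shuffled["significant"] = True
        shuffled["sign"] = "none"
        pvals.append(gxgxe_test(shuffled).p)
    # under label permutation the p-values should be roughly uniform
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 1e-3


def test_gxgxe_rejects_unbalanced():
    est = two_env_estimates(0.5, 2.0)
    with pytest.raises(ValueError):
        gxgxe_test(pd.concat([est, est.iloc[[0]].assign(double="x")], ignore_index=True))


# ---------------------------------------------------------------------------
# conformity

def test_conformity_perfect_agreement():
    est = sig_frame(5, 5)
    predicted = {
        d: (EpistasisSign.POSITIVE if d.startswith("p") else EpistasisSign.NEGATIVE)
        for d in est["double"]
    }
    res = conformity_test(predicted, est)
    assert res.agreement == pytest.approx(1.0)
    assert res.chi2 == pytest.approx(0.0)


def test_conformity_random_predictions_near_half(default_estimates):
    _, est = default_estimates
    sig = est[est["significant"]]
    rng = np.random.default_rng(23)
    predicted = {
        d: (EpistasisSign.POSITIVE if rng.random() < 0.5 else EpistasisSign.NEGATIVE)
        for d in sig["double"].unique()
    }
    res = conformity_test(predicted, est, environment=ENV_REPRESSOR)
    assert 0.3 < res.agreement < 0.7


def test_conformity_requires_overlap():
    with pytest.raises(ValueError):
        conformity_test({"zzz": EpistasisSign.POSITIVE}, sig_frame(2, 2))


def test_predict_signs_from_singles_rules():
    norm = normalize(
        make_fluor({"WT": 1.0, "m1": 0.5, "m2": 0.4, "m3": 1.5, "m4": 1.0,
                    "d12": 0.3, "d13": 0.9, "d14": 0.5})
    )
    pairs = pd.DataFrame(
        [
            {"double": "d12", "single1": "m1", "single2": "m2"},
            {"double": "d13", "single1": "m1", "single2": "m3"},
            {"double": "d14", "single1": "m1", "single2": "m4"},
        ]
    )
    pred = predict_signs_from_singles(norm, pairs)
    assert pred["d12"] is EpistasisSign.NEGATIVE  # same direction
    assert pred["d13"] is EpistasisSign.POSITIVE  # opposite directions
    assert pred["d14"] is EpistasisSign.NONE  # neutral single


def test_conformity_on_model_predictions(default_estimates):
    # the paper's procedure: predict no-repressor signs from measured
    # single-mutant directions, compare to significant observed signs
    norm, est = default_estimates
    study_pairs = est[["double"]].drop_duplicates()
    pairs = pd.DataFrame(
        {
            "double": study_pairs["double"],
            "single1": [d.split("_")[0] for d in study_pairs["double"]],
            "single2": [d.split("_")[1] for d in study_pairs["double"]],
        }
    )
    pred = predict_signs_from_singles(norm, pairs)
    res = conformity_test(pred, est, environment=ENV_REPRESSOR, significant_only=True)
    assert 0.0 <= res.agreement <= 1.0
    assert res.n > 0
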