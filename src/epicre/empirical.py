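"""Epistasis estimation from replicate fluorescence measurements.

The pipeline mirrors a standard reporter-assay design: raw fluorescence of
single and double mutants, measured in replicate in two environments
(repressor absent / present), is blank-corrected and normalized by the
wildtype; multiplicative epistasis eps = f_m12 / (f_m1 f_m2) is then
estimated per double mutant with a delta-method standard error on
log eps, tested against eps = 1 with FDR correction, classified by type
(magnitude / sign / reciprocal sign), and summarised at cohort level
(sign bias, environment dependence, conformity with model predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import Genotype
from .thermo import EpistasisSign

__all__ = [
    "ENV_NO_REPRESSOR",
    "ENV_REPRESSOR",
    "EpistasisClass",
    "SignBiasResult",
    "GxGxEResult",
    "ConformityResult",
    "pairs_from_genotypes",
    "normalize",
    "estimate_epistasis",
    "classify_type",
    "classify_types",
    "environment_comparison",
    "sign_bias_test",
    "gxgxe_test",
    "conformity_test",
    "predict_signs_from_singles",
]

ENV_NO_REPRESSOR = "no_repressor"
ENV_REPRESSOR = "repressor"

WILDTYPE_ID = "WT"
BLANK_ID = "blank"

FLUOR_COLUMNS = ("genotype", "environment", "replicate", "fluorescence")


class EpistasisClass(Enum):
    NO_EPISTASIS = "no_epistasis"
    POSITIVE_MAGNITUDE = "positive_magnitude"
    NEGATIVE_MAGNITUDE = "negative_magnitude"
    SIGN = "sign"
    RECIPROCAL_SIGN = "reciprocal_sign"


def pairs_from_genotypes(genotypes: Iterable[Genotype]) -> pd.DataFrame:
    """Map each double mutant to its two single mutants by mutation identity.

    Returns a DataFrame with columns ``double``, ``single1``, ``single2``.
    Requires both constituent singles to be present in ``genotypes``.
    """
    by_mutations = {g.mutations: g.id for g in genotypes}
    rows = []
    for g in genotypes:
        if g.n_mutations != 2:
            continue
        singles = []
        for m in g.mutations:
            try:
                singles.append(by_mutations[(m,)])
            except KeyError:
                raise ValueError(
                    f"double mutant {g.id!r}: single mutant for {m.label} not in the library"
                ) from None
        rows.append({"double": g.id, "single1": singles[0], "single2": singles[1]})
    return pd.DataFrame(rows, columns=["double", "single1", "single2"])


# ---------------------------------------------------------------------------
# Normalization

def normalize(
    fluor: pd.DataFrame,
    wildtype: str = WILDTYPE_ID,
    blank: str = BLANK_ID,
    floor_frac: float = 1e-4,
) -> pd.DataFrame:
    """Wildtype-relative expression with delta-method uncertainty.

    ``fluor`` is tidy with columns genotype, environment, replicate,
    fluorescence (raw arbitrary units; rows with genotype == ``blank`` are
    media autofluorescence). Per environment,

        f = (mean - blank) / (mean_WT - blank)

    and the squared relative error of f (``relvar``, variance of log f)
    is the sum of the squared relative standard errors of the
    blank-corrected mutant and wildtype means. Non-positive corrected
    means are floored at ``floor_frac`` of the corrected wildtype with a
    warning (column ``floored``).
    """
    missing = [c for c in FLUOR_COLUMNS if c not in fluor.columns]
    if missing:
        raise ValueError(f"fluorescence table lacks columns {missing}")
    if (fluor["fluorescence"] < 0).any():
        raise ValueError("raw fluorescence must be >= 0")

    out_frames = []
    for env, sub in fluor.groupby("environment", sort=False):
        stats_df = sub.groupby("genotype")["fluorescence"].agg(["mean", "var", "count"])
        stats_df["var"] = stats_df["var"].fillna(0.0)
        if (stats_df["count"] < 2).any():
            bad = stats_df.index[stats_df["count"] < 2].tolist()
            raise ValueError(f"environment {env!r}: genotypes with < 2 replicates: {bad}")
        blank_mean = float(stats_df.loc[blank, "mean"]) if blank in stats_df.index else 0.0
        stats_df = stats_df.drop(index=blank, errors="ignore")
        if wildtype not in stats_df.index:
            raise ValueError(f"environment {env!r}: wildtype {wildtype!r} missing")
        wt_corr = stats_df.loc[wildtype, "mean"] - blank_mean
        if wt_corr <= 0:
            raise ValueError(f"environment {env!r}: wildtype mean does not exceed the blank")
        wt_relvar = float(
            stats_df.loc[wildtype, "var"] / stats_df.loc[wildtype, "count"] / wt_corr**2
        )

        corrected = stats_df["mean"] - blank_mean
        floored = corrected <= 0
        if floored.any():
            warnings.warn(
                f"environment {env!r}: {int(floored.sum())} genotype(s) at or below the blank; "
                f"floored at {floor_frac} of wildtype",
                stacklevel=2,
            )
            corrected = corrected.where(~floored, floor_frac * wt_corr)
        sem2 = stats_df["var"] / stats_df["count"]
        env_out = pd.DataFrame(
            {
                "environment": env,
                "n": stats_df["count"].astype(int),
                "mean": stats_df["mean"],
                "sd": np.sqrt(stats_df["var"]),
                "f": corrected / wt_corr,
                "relvar": sem2 / corrected**2 + wt_relvar,
                "floored": floored,
            }
        )
        env_out["f_sd"] = env_out["f"] * np.sqrt(env_out["relvar"])
        out_frames.append(env_out)

    out = pd.concat(out_frames)
    out.index.name = "genotype"
    return out.set_index("environment", append=True)


# ---------------------------------------------------------------------------
# Per-double-mutant epistasis estimates

def estimate_epistasis(
    norm: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multiplicative epistasis per double mutant and environment.

    eps = f_m12 / (f_m1 f_m2); var(log eps) is the sum of the three
    normalized values' ``relvar`` terms (the wildtype contribution enters
    through each, a conservative propagation); t = log eps / sd(log eps)
    with df = n - 1 replicates; two-sided p-values are Benjamini-Hochberg
    corrected across the double mutants within each environment. The sign
    is POSITIVE/NEGATIVE only for significant estimates.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for env in norm.index.get_level_values("environment").unique():
        sub = norm.xs(env, level="environment")
        missing = (
            set(pairs["double"]) | set(pairs["single1"]) | set(pairs["single2"])
        ) - set(sub.index)
        if missing:
            raise ValueError(f"environment {env!r}: genotypes missing from data: {sorted(missing)}")
        f1 = sub.loc[pairs["single1"], "f"].to_numpy()
        f2 = sub.loc[pairs["single2"], "f"].to_numpy()
        f12 = sub.loc[pairs["double"], "f"].to_numpy()
        if (f1 <= 0).any() or (f2 <= 0).any() or (f12 <= 0).any():
            raise ValueError("all relative expressions must be > 0 (floor non-positive values)")
        relvar = (
            sub.loc[pairs["single1"], "relvar"].to_numpy()
            + sub.loc[pairs["single2"], "relvar"].to_numpy()
            + sub.loc[pairs["double"], "relvar"].to_numpy()
        )
        n = sub.loc[pairs["double"], "n"].to_numpy()
        log_eps = np.log(f12) - np.log(f1) - np.log(f2)
        sd_log = np.sqrt(relvar)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd_log > 0, log_eps / sd_log, np.where(log_eps == 0, 0.0, np.inf * np.sign(log_eps)))
        df = n - 1
        p = 2 * stats.t.sf(np.abs(t), df)
        rows.append(
            pd.DataFrame(
                {
                    "double": pairs["double"].to_numpy(),
                    "environment": env,
                    "f_m1": f1,
                    "f_m2": f2,
                    "f_m12": f12,
                    "epsilon": np.exp(log_eps),
                    "log_epsilon": log_eps,
                    "sd_log_epsilon": sd_log,
                    "sd_epsilon": np.exp(log_eps) * sd_log,
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
        )
    est = pd.concat(rows, ignore_index=True)
    est["q"] = np.nan
    for env, idx in est.groupby("environment").groups.items():
        est.loc[idx, "q"] = multipletests(est.loc[idx, "p"], alpha=alpha, method="fdr_bh")[1]
    est["significant"] = est["q"] <= alpha
    est["sign"] = np.where(
        ~est["significant"],
        EpistasisSign.NONE.value,
        np.where(est["log_epsilon"] > 0, EpistasisSign.POSITIVE.value, EpistasisSign.NEGATIVE.value),
    )
    return est


# ---------------------------------------------------------------------------
# Epistasis-type classification

def _flip(f_own: float, f_other: float, f_double: float) -> bool:
    """Does this mutation's effect reverse on the other single's background?"""
    on_wt = np.sign(f_own - 1.0)
    on_other = np.sign(f_double / f_other - 1.0)
    return bool(on_wt != 0 and on_other != 0 and on_wt != on_other)


def classify_type(
    f_m1: float, f_m2: float, f_m12: float, significant: bool = True
) -> tuple[EpistasisClass, bool]:
    """Epistasis type from the three relative expressions.

    Returns (class, flip_without_significance). A mutation "flips" when
    its effect direction on the wildtype background (f_mi vs 1) reverses
    on the other single's background (f_m12/f_mj vs 1); two flips give
    reciprocal sign epistasis, one gives sign epistasis, none gives
    magnitude epistasis by eps vs 1. Non-significant estimates are
    classified NO_EPISTASIS, with the second return flagging flips that
    were present but not statistically supported.
    """
    if min(f_m1, f_m2, f_m12) <= 0:
        raise ValueError("relative expressions must be > 0")
    flips = _flip(f_m1, f_m2, f_m12) + _flip(f_m2, f_m1, f_m12)
    if not significant:
        return EpistasisClass.NO_EPISTASIS, flips > 0
    if flips == 2:
        return EpistasisClass.RECIPROCAL_SIGN, False
    if flips == 1:
        return EpistasisClass.SIGN, False
    eps = f_m12 / (f_m1 * f_m2)
    if eps > 1:
        return EpistasisClass.POSITIVE_MAGNITUDE, False
    return EpistasisClass.NEGATIVE_MAGNITUDE, False


def classify_types(est: pd.DataFrame) -> pd.DataFrame:
    """Add ``epistasis_class`` / ``flip_without_significance`` columns to estimates."""
    classes, caveats = [], []
    for row in est.itertuples():
        cls, caveat = classify_type(row.f_m1, row.f_m2, row.f_m12, row.significant)
        classes.append(cls.value)
        caveats.append(caveat)
    out = est.copy()
    out["epistasis_class"] = classes
    out["flip_without_significance"] = caveats
    return out


# ---------------------------------------------------------------------------
# Cohort-level statistics

def environment_comparison(
    est: pd.DataFrame,
    env_a: str = ENV_NO_REPRESSOR,
    env_b: str = ENV_REPRESSOR,
    lenient: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-mutant sign change between two environments plus cohort summary.

    With ``lenient=False`` only mutants significant in both environments
    get a changed/unchanged call; others are 'indeterminate'. With
    ``lenient=True`` point-estimate signs (eps vs 1) are used for every
    mutant. ``delta_log10`` is log10(eps_b) - log10(eps_a), the
    environment-shift coordinate.
    """
    a = est[est["environment"] == env_a].set_index("double")
    b = est[est["environment"] == env_b].set_index("double")
    common = a.index.intersection(b.index)
    dropped = a.index.symmetric_difference(b.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} mutant(s) lack an estimate in one environment and were excluded",
            stacklevel=2,
        )
    a, b = a.loc[common], b.loc[common]

    def env_sign(sub: pd.DataFrame) -> pd.Series:
        if lenient:
            return pd.Series(
                np.where(sub["log_epsilon"] > 0, "positive",
                         np.where(sub["log_epsilon"] < 0, "negative", "none")),
                index=sub.index,
            )
        return sub["sign"]

    sign_a, sign_b = env_sign(a), env_sign(b)
    comparable = (sign_a != "none") & (sign_b != "none")
    changed = np.where(comparable, np.where(sign_a != sign_b, "yes", "no"), "indeterminate")
    per_mutant = pd.DataFrame(
        {
            "sign_" + env_a: sign_a,
            "sign_" + env_b: sign_b,
            "log10_eps_" + env_a: a["log_epsilon"] / np.log(10),
            "log10_eps_" + env_b: b["log_epsilon"] / np.log(10),
            "delta_log10": (b["log_epsilon"] - a["log_epsilon"]) / np.log(10),
            "changed": changed,
            "significant_both": (a["significant"] & b["significant"]),
        },
        index=common,
    )
    n_comparable = int(comparable.sum())
    summary = {
        "n": int(len(per_mutant)),
        "n_comparable": n_comparable,
        "n_changed": int((per_mutant["changed"] == "yes").sum()),
        "n_always_positive": int(((sign_a == "positive") & (sign_b == "positive")).sum()),
        "n_always_negative": int(((sign_a == "negative") & (sign_b == "negative")).sum()),
        "n_indeterminate": int((per_mutant["changed"] == "indeterminate").sum()),
        "n_significant_both": int(per_mutant["significant_both"].sum()),
        "changed_fraction": float((per_mutant["changed"] == "yes").sum() / n_comparable)
        if n_comparable
        else float("nan"),
    }
    return per_mutant, summary


@dataclass(frozen=True)
class SignBiasResult:
    chi2: float
    df: int
    p: float
    n_positive: int
    n_negative: int


def sign_bias_test(est: pd.DataFrame, environment: str | None = None) -> SignBiasResult:
    """Pearson chi-squared test for a bias toward one sign of epistasis.

    Observed counts of significant positive vs negative estimates are
    tested against equal expected proportions.
    """
    sub = est if environment is None else est[est["environment"] == environment]
    sig = sub[sub["significant"]]
    if sig.empty:
        raise ValueError("no significant epistasis estimates to test")
    n_pos = int((sig["sign"] == EpistasisSign.POSITIVE.value).sum())
    n_neg = int((sig["sign"] == EpistasisSign.NEGATIVE.value).sum())
    chi2, p = stats.chisquare([n_pos, n_neg])
    return SignBiasResult(float(chi2), 1, float(p), n_pos, n_neg)


@dataclass(frozen=True)
class GxGxEResult:
    F: float
    df_num: int
    df_den: int
    p: float


def gxgxe_test(
    est: pd.DataFrame,
    env_a: str = ENV_NO_REPRESSOR,
    env_b: str = ENV_REPRESSOR,
) -> GxGxEResult:
    """ANOVA for a genotype x genotype x environment interaction.

    The deviation of each double mutant from the multiplicative
    expectation (log eps) is compared between the two environments; a
    significant environment effect means the mutation interaction itself
    depends on the environment. One-way F with df (1, 2n - 2) for n pairs.
    """
    a = est[est["environment"] == env_a].set_index("double")["log_epsilon"]
    b = est[est["environment"] == env_b].set_index("double")["log_epsilon"]
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(f"mutants missing from one environment: {sorted(missing)}")
    if len(a) < 2:
        raise ValueError("need at least two double mutants per environment")
    F, p = stats.f_oneway(a.to_numpy(), b.to_numpy())
    return GxGxEResult(float(F), 1, int(len(a) + len(b) - 2), float(p))


@dataclass(frozen=True)
class ConformityResult:
    chi2: float
    df: int
    p: float
    agreement: float
    n: int


def conformity_test(
    predicted: Mapping[str, EpistasisSign],
    est: pd.DataFrame,
    environment: str | None = None,
    significant_only: bool = True,
) -> ConformityResult:
    """Do observed epistasis signs follow the model-predicted distribution?

    Restricted to double mutants with significant observed epistasis (the
    model predicts where epistasis points, not whether noise hides it).
    Pearson chi-squared compares the observed positive/negative counts to
    the distribution of predicted signs among the same mutants; agreement
    is the per-mutant match fraction.
    """
    sub = est if environment is None else est[est["environment"] == environment]
    if significant_only:
        sub = sub[sub["significant"]]
    sub = sub[sub["double"].isin(predicted.keys())]
    if sub.empty:
        raise ValueError("no overlap between predictions and (significant) observations")
    pred = np.array([predicted[d].value for d in sub["double"]])
    keep = pred != EpistasisSign.NONE.value
    pred, obs = pred[keep], sub["sign"].to_numpy()[keep]
    if len(pred) == 0:
        raise ValueError("all predictions are 'none'; nothing to compare")
    labels = [EpistasisSign.POSITIVE.value, EpistasisSign.NEGATIVE.value]
    obs_counts = np.array([(obs == lab).sum() for lab in labels])
    pred_counts = np.array([(pred == lab).sum() for lab in labels])
    if (pred_counts == 0).any():
        # collapse to the single predicted class; chi2 degenerates to a
        # one-cell comparison which is only informative through agreement
        chi2, p, dof = float("nan"), float("nan"), 0
    else:
        expected = pred_counts * obs_counts.sum() / pred_counts.sum()
        chi2, p = stats.chisquare(obs_counts, f_exp=expected)
        dof = 1
    agreement = float((pred == obs).mean())
    return ConformityResult(float(chi2), dof, float(p), agreement, int(len(pred)))


def predict_signs_from_singles(
    norm: pd.DataFrame,
    pairs: pd.DataFrame,
    environment: str = ENV_NO_REPRESSOR,
) -> dict[str, EpistasisSign]:
    """Repressor-free sign predictions from measured single-mutant directions.

    A single mutant's effect direction is sign(f - 1); two same-direction
    mutations are predicted in negative epistasis, opposite directions in
    positive epistasis, and a neutral single yields no prediction.
    """
    sub = norm.xs(environment, level="environment")
    out: dict[str, EpistasisSign] = {}
    for row in pairs.itertuples():
        s1 = np.sign(sub.loc[row.single1, "f"] - 1.0)
        s2 = np.sign(sub.loc[row.single2, "f"] - 1.0)
        if s1 == 0 or s2 == 0:
            out[row.double] = EpistasisSign.NONE
        elif s1 == s2:
            out[row.double] = EpistasisSign.NEGATIVE
        else:
            out[row.double] = EpistasisSign.POSITIVE
    return out
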