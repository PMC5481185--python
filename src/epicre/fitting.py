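"""Predict epistasis from energy matrices and fit effective TF activities.

Per-mutant epistasis predictions compose the additive energy-matrix
effects with the closed-form thermodynamic epistasis. The two free
parameters — effective RNAP and repressor activities P and R — are
estimated by maximizing the Pearson correlation between predicted and
measured log epistasis over both environments jointly (R = 0 in the
repressor-free environment), then summarised by a per-environment linear
regression of measured on predicted log epistasis.

Only the products B = P e^{-E_P} and A = R e^{-E_R} are identifiable:
the baseline energies are absorbed into the fitted activities, so P_hat
and R_hat are reported relative to the supplied E_P, E_R.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .empirical import ENV_NO_REPRESSOR, ENV_REPRESSOR
from .matrices import EnergyMatrix, Genotype, Mutation, mutation_effects
from .thermo import MutationEffect, ThermoParams, log_epistasis_array, thermo_epistasis

__all__ = [
    "FitResult",
    "predict_library",
    "make_epistasis_predictor",
    "fit_concentrations",
]


@dataclass(frozen=True)
class FitResult:
    P_hat: float
    R_hat: float
    objective: float  # Pearson correlation achieved on log epsilon
    per_environment: dict[str, dict[str, float]]  # slope/intercept/F/df/p
    n_used: int
    excluded: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.P_hat <= 0 or self.R_hat <= 0:
            raise ValueError("fitted activities must be > 0")
        if not -1.0 <= self.objective <= 1.0 + 1e-12:
            raise ValueError("objective must be a correlation in [-1, 1]")


def _double_effects(
    genotypes: Sequence[Genotype],
    rnap: EnergyMatrix,
    repressor: EnergyMatrix,
    wt_seq: str,
) -> pd.DataFrame:
    """Per-double-mutant single-mutation effects (p1, r1, p2, r2)."""
    rows = []
    for g in genotypes:
        if g.n_mutations != 2:
            continue
        effs = [
            mutation_effects(Genotype(m.label, (m,)), rnap, repressor, wt_seq)
            for m in g.mutations
        ]
        rows.append(
            {"double": g.id, "p1": effs[0].p, "r1": effs[0].r, "p2": effs[1].p, "r2": effs[1].r}
        )
    if not rows:
        raise ValueError("no double mutants among the genotypes")
    return pd.DataFrame(rows).set_index("double")


def predict_library(
    genotypes: Sequence[Genotype],
    rnap: EnergyMatrix,
    repressor: EnergyMatrix,
    wt_seq: str,
    params: ThermoParams,
) -> pd.DataFrame:
    """Predicted epistasis for every double mutant at the given activities.

    In a repressor-free environment pass ``params`` with R = 0; the
    prediction then depends only on the RNAP matrix.
    """
    eff = _double_effects(genotypes, rnap, repressor, wt_seq)
    log_eps = log_epistasis_array(
        params.log_A, params.log_B,
        eff["p1"].to_numpy(), eff["r1"].to_numpy(),
        eff["p2"].to_numpy(), eff["r2"].to_numpy(),
    )
    if params.P == 0:
        raise ValueError("epistasis prediction requires P > 0")
    return pd.DataFrame(
        {"log_epsilon_pred": log_eps, "epsilon_pred": np.exp(log_eps)}, index=eff.index
    )


def make_epistasis_predictor(
    genotypes: Sequence[Genotype],
    rnap: EnergyMatrix,
    repressor: EnergyMatrix,
    wt_seq: str,
    E_P: float = 0.0,
    E_R: float = 0.0,
    environments: dict[str, bool] | None = None,
) -> Callable[[float, float], pd.DataFrame]:
    """Closure mapping activities (P, R) to predicted log epsilon per mutant.

    ``environments`` maps environment label -> repressor present?; the
    repressor-free environment is evaluated at R = 0. Returns a tidy
    DataFrame with columns double, environment, log_epsilon_pred.
    """
    if environments is None:
        environments = {ENV_NO_REPRESSOR: False, ENV_REPRESSOR: True}
    eff = _double_effects(genotypes, rnap, repressor, wt_seq)
    p1, r1 = eff["p1"].to_numpy(), eff["r1"].to_numpy()
    p2, r2 = eff["p2"].to_numpy(), eff["r2"].to_numpy()

    def predict(P: float, R: float) -> pd.DataFrame:
        frames = []
        for env, has_rep in environments.items():
            params = ThermoParams(E_P, E_R, P, R if has_rep else 0.0)
            log_eps = log_epistasis_array(params.log_A, params.log_B, p1, r1, p2, r2)
            frames.append(
                pd.DataFrame(
                    {"double": eff.index, "environment": env, "log_epsilon_pred": log_eps}
                )
            )
        return pd.concat(frames, ignore_index=True)

    return predict


def _regressions(merged: pd.DataFrame) -> dict[str, dict[str, float]]:
    out = {}
    for env, sub in merged.groupby("environment"):
        if len(sub) < 3 or np.ptp(sub["log_epsilon_pred"].to_numpy()) == 0:
            out[env] = {k: float("nan") for k in ("slope", "intercept", "r", "F", "df_num", "df_den", "p", "n")}
            out[env]["n"] = float(len(sub))
            continue
        res = stats.linregress(sub["log_epsilon_pred"], sub["log_epsilon"])
        n = len(sub)
        F = res.rvalue**2 * (n - 2) / (1 - res.rvalue**2) if abs(res.rvalue) < 1 else float("inf")
        out[env] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r": float(res.rvalue),
            "F": float(F),
            "df_num": 1.0,
            "df_den": float(n - 2),
            "p": float(res.pvalue),
            "n": float(n),
        }
    return out


def fit_concentrations(
    predictor: Callable[[float, float], pd.DataFrame],
    measured: pd.DataFrame,
    significant_only: bool = True,
    n_grid: int = 25,
    log10_bounds: tuple[float, float] = (-6.0, 6.0),
) -> FitResult:
    """Estimate activities (P, R) by correlation maximization.

    A coarse ``n_grid`` x ``n_grid`` search over log10 P, log10 R inside
    ``log10_bounds`` is followed by Nelder-Mead refinement of the Pearson
    correlation between predicted and measured log epsilon, pooled over
    environments. ``measured`` needs columns double, environment,
    log_epsilon and (for filtering) significant. Deterministic.
    """
    cols = {"double", "environment", "log_epsilon"}
    if not cols.issubset(measured.columns):
        raise ValueError(f"measured estimates need columns {sorted(cols)}")
    excluded: tuple[str, ...] = ()
    if significant_only:
        if "significant" not in measured.columns:
            raise ValueError("significant_only=True requires a 'significant' column")
        excluded = tuple(sorted(set(measured.loc[~measured["significant"], "double"])))
        measured = measured[measured["significant"]]
    if measured["double"].nunique() < 3:
        raise ValueError("need at least 3 double mutants after filtering")
    measured = measured[["double", "environment", "log_epsilon"]]

    def objective(log10_P: float, log10_R: float) -> float:
        pred = predictor(10.0**log10_P, 10.0**log10_R)
        merged = measured.merge(pred, on=["double", "environment"], how="inner")
        x = merged["log_epsilon_pred"].to_numpy()
        if len(merged) < 3:
            raise ValueError("fewer than 3 matched prediction/measurement pairs")
        if np.ptp(x) == 0:
            return -np.inf  # degenerate: all predictions identical
        return float(stats.pearsonr(x, merged["log_epsilon"])[0])

    lo, hi = log10_bounds
    grid = np.linspace(lo, hi, n_grid)
    best, best_xy = -np.inf, (grid[0], grid[0])
    for lp, lr in itertools.product(grid, grid):
        val = objective(lp, lr)
        if val > best:
            best, best_xy = val, (lp, lr)
    if not np.isfinite(best):
        raise ValueError("degenerate predictions: no parameter point gives varying epistasis")

    res = optimize.minimize(
        lambda xy: -objective(xy[0], xy[1]),
        x0=np.array(best_xy),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 800},
    )
    lp, lr = (res.x if -res.fun >= best else np.array(best_xy))
    P_hat, R_hat = float(10.0**lp), float(10.0**lr)

    pred = predictor(P_hat, R_hat)
    merged = measured.merge(pred, on=["double", "environment"], how="inner")
    return FitResult(
        P_hat=P_hat,
        R_hat=R_hat,
        objective=max(float(-res.fun), best),
        per_environment=_regressions(merged),
        n_used=int(merged["double"].nunique()),
        excluded=excluded,
    )
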