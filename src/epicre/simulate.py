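"""Synthetic reporter-assay studies with known thermodynamic ground truth.

Generates everything the empirical pipeline consumes — a wildtype CRE,
energy matrices for the two competing proteins, a random single/double
mutant library, and replicate fluorescence in two environments — from a
seeded configuration, together with a ground-truth table computed
directly from the thermodynamic model (never read by the pipeline under
test).

Default geometry emulates a canonical repressible promoter: a 43-bp CRE
whose RNAP site occupies the 5' 30 bp and whose repressor footprint (two
operator half-sites tiling the downstream promoter) covers positions
9-42, so the two sites overlap heavily and most positions affect both
proteins. 141 random double mutants with all their singles, six
replicates each, lognormal multiplicative noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .empirical import ENV_NO_REPRESSOR, ENV_REPRESSOR, BLANK_ID, WILDTYPE_ID, pairs_from_genotypes
from .matrices import BASES, EnergyMatrix, Genotype, Mutation, mutation_effects
from .thermo import (
    EpistasisSign,
    MutationEffect,
    ThermoParams,
    log_epistasis,
    p_on,
)

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "sample_wildtype_sequence",
    "sample_energy_matrix",
    "sample_library",
    "simulate_fluorescence",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and model parameters for a synthetic experiment.

    noise_sd is the standard deviation of the lognormal multiplicative
    replicate noise (roughly the replicate coefficient of variation);
    blank_level is the media autofluorescence as a fraction of the
    wildtype signal. The repressor-present environment uses activity
    R_repressor (A = R e^{-E_R} = 100 by default, ~30-fold repression of
    a strong promoter with B = 2.5); the repressor-free environment uses
    R = 0.
    """

    seed: int = 0
    cre_length: int = 43
    n_doubles: int = 141
    replicates: int = 6
    noise_sd: float = 0.1
    blank_level: float = 0.05
    wildtype_scale: float = 1.0
    E_P: float = 0.0
    E_R: float = 0.0
    P: float = 2.5
    R_repressor: float = 100.0
    matrix_scale: float = 2.0  # mean RNAP mismatch penalty, kT
    repressor_scale: float = 3.0  # mean repressor mismatch penalty, kT
    improving_fraction: float = 0.25  # positions where one base binds better than wildtype
    rnap_offset: int = 0
    rnap_length: int = 30
    rep_offset: int = 9
    rep_length: int = 34
    environments: tuple[str, ...] = (ENV_NO_REPRESSOR, ENV_REPRESSOR)

    def __post_init__(self) -> None:
        if min(self.cre_length, self.n_doubles, self.replicates) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.improving_fraction < 1.0:
            raise ValueError("improving_fraction must be in [0, 1)")
        if self.rnap_offset + self.rnap_length > self.cre_length:
            raise ValueError("RNAP footprint exceeds the CRE")
        if self.rep_offset + self.rep_length > self.cre_length:
            raise ValueError("repressor footprint exceeds the CRE")
        overlap = min(self.rnap_offset + self.rnap_length, self.rep_offset + self.rep_length) - max(
            self.rnap_offset, self.rep_offset
        )
        if overlap <= 0:
            raise ValueError("footprints must overlap: competition requires shared positions")

    def params(self, environment: str) -> ThermoParams:
        R = self.R_repressor if environment == ENV_REPRESSOR else 0.0
        return ThermoParams(self.E_P, self.E_R, self.P, R)


def sample_wildtype_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def sample_energy_matrix(
    length: int,
    scale: float,
    seed: int,
    reference: str | None = None,
    offset: int = 0,
    name: str = "synthetic",
    improving_fraction: float = 0.0,
) -> EnergyMatrix:
    """Random energy matrix anchored to a reference sequence.

    Reference-base entries are 0; every mismatch entry is drawn from a
    Gaussian of mean ``scale`` (kT) truncated at 0, so most mutations
    weaken binding — a stand-in for the matrix of a strong, specific
    site. At a random ``improving_fraction`` of positions one non-
    reference base instead gets a negative entry, emulating a wildtype
    site that is near, but not at, the matrix optimum (real strong
    promoters and operators carry a few sub-consensus bases).
    Deterministic for a given seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if not 0.0 <= improving_fraction < 1.0:
        raise ValueError("improving_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = "".join(rng.choice(list(BASES), size=length))
    if len(reference) != length:
        raise ValueError("reference length must equal matrix length")
    entries = np.zeros((length, 4))
    if scale > 0:
        sd = scale / 2.0
        entries = sps.truncnorm.rvs(
            a=-scale / sd, b=np.inf, loc=scale, scale=sd, size=(length, 4), random_state=rng
        )
        for i in range(length):
            if rng.random() < improving_fraction:
                j = int(rng.integers(0, 4))
                entries[i, j] = -abs(rng.normal(0.5 * scale, 0.25 * scale))
    for i, b in enumerate(reference):
        entries[i, BASES.index(b)] = 0.0
    return EnergyMatrix(name=name, entries=entries, reference_sequence=reference, offset=offset)


def sample_library(wt_seq: str, n_doubles: int, seed: int) -> list[Genotype]:
    """Random double mutants plus all of their single mutants, deduplicated.

    Doubles are drawn uniformly without replacement from all pairs of
    single substitutions at distinct positions; every double's two singles
    are included exactly once. The wildtype genotype is included first.
    """
    singles = [
        Mutation(pos, ref, alt)
        for pos, ref in enumerate(wt_seq)
        for alt in BASES
        if alt != ref
    ]
    pairs = [
        (a, b)
        for i, a in enumerate(singles)
        for b in singles[i + 1 :]
        if a.position != b.position
    ]
    if n_doubles > len(pairs):
        raise ValueError(f"requested {n_doubles} doubles but only {len(pairs)} distinct pairs exist")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(pairs), size=n_doubles, replace=False))
    genotypes: list[Genotype] = [Genotype(WILDTYPE_ID)]
    seen_singles: set[Mutation] = set()
    for i in chosen:
        a, b = pairs[int(i)]
        for m in (a, b):
            if m not in seen_singles:
                seen_singles.add(m)
                genotypes.append(Genotype(m.label, (m,)))
        genotypes.append(Genotype(f"{a.label}_{b.label}", (a, b)))
    return genotypes


def simulate_fluorescence(
    config: SimulationConfig,
    genotypes: list[Genotype],
    rnap: EnergyMatrix,
    repressor: EnergyMatrix,
    wt_seq: str,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate fluorescence plus the model ground truth per genotype.

    Mean fluorescence is blank + wildtype_scale * p_ON(g) / p_ON(WT) per
    environment; replicates carry lognormal(0, noise_sd) multiplicative
    noise. The ground-truth table holds p_ON, the true relative
    expression, and — for double mutants — the true epistasis and its
    sign.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effects = {g.id: mutation_effects(g, rnap, repressor, wt_seq) for g in genotypes}
    by_id = {g.id: g for g in genotypes}

    fluor_rows, truth_rows = [], []
    for env in config.environments:
        params = config.params(env)
        pon_wt = p_on(params)
        for g in genotypes:
            eff = effects[g.id]
            pon = p_on(params, eff)
            f_true = pon / pon_wt
            mean = config.blank_level + config.wildtype_scale * f_true
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=config.replicates)) if config.noise_sd > 0 else np.ones(config.replicates)
            for k, v in enumerate(mean * noise):
                fluor_rows.append((g.id, env, k + 1, float(v)))
            truth = {
                "genotype": g.id,
                "environment": env,
                "n_mutations": g.n_mutations,
                "p": eff.p,
                "r": eff.r,
                "p_on": pon,
                "f_true": f_true,
            }
            if g.n_mutations == 2:
                m1, m2 = (MutationEffect(*e) for e in _split_effects(g, rnap, repressor, wt_seq))
                le = log_epistasis(params, m1, m2)
                truth["epsilon_true"] = math.exp(le)
                truth["sign_true"] = (
                    EpistasisSign.POSITIVE.value
                    if le > 1e-12
                    else EpistasisSign.NEGATIVE.value
                    if le < -1e-12
                    else EpistasisSign.NONE.value
                )
            truth_rows.append(truth)
        # blank wells, measured with the same multiplicative noise
        blank_noise = np.exp(rng.normal(0.0, config.noise_sd, size=config.replicates)) if config.noise_sd > 0 else np.ones(config.replicates)
        for k, v in enumerate(config.blank_level * blank_noise):
            fluor_rows.append((BLANK_ID, env, k + 1, float(v)))

    fluor = pd.DataFrame(fluor_rows, columns=["genotype", "environment", "replicate", "fluorescence"])
    truth = pd.DataFrame(truth_rows)
    return fluor, truth


def _split_effects(g: Genotype, rnap, repressor, wt_seq) -> list[tuple[float, float]]:
    out = []
    for m in g.mutations:
        e = mutation_effects(Genotype(m.label, (m,)), rnap, repressor, wt_seq)
        out.append((e.p, e.r))
    return out


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete simulated experiment with its ground truth."""

    config: SimulationConfig
    wt_seq: str
    rnap: EnergyMatrix
    repressor: EnergyMatrix
    genotypes: tuple[Genotype, ...]
    pairs: pd.DataFrame
    fluorescence: pd.DataFrame
    truth: pd.DataFrame


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate matrices, library and fluorescence from one seeded config."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    wt_seq = sample_wildtype_sequence(config.cre_length, int(seeds[0]))
    rnap = sample_energy_matrix(
        config.rnap_length,
        config.matrix_scale,
        int(seeds[1]),
        reference=wt_seq[config.rnap_offset : config.rnap_offset + config.rnap_length],
        offset=config.rnap_offset,
        name="rnap_synthetic",
        improving_fraction=config.improving_fraction,
    )
    repressor = sample_energy_matrix(
        config.rep_length,
        config.repressor_scale,
        int(seeds[2]),
        reference=wt_seq[config.rep_offset : config.rep_offset + config.rep_length],
        offset=config.rep_offset,
        name="repressor_synthetic",
        improving_fraction=config.improving_fraction,
    )
    genotypes = sample_library(wt_seq, config.n_doubles, int(seeds[3]))
    fluor, truth = simulate_fluorescence(
        config, genotypes, rnap, repressor, wt_seq, rng=np.random.default_rng(int(seeds[3]) + 1)
    )
    return SyntheticStudy(
        config=config,
        wt_seq=wt_seq,
        rnap=rnap,
        repressor=repressor,
        genotypes=tuple(genotypes),
        pairs=pairs_from_genotypes(genotypes),
        fluorescence=fluor,
        truth=truth,
    )
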