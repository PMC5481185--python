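"""Position-specific binding-energy matrices and genotypes on a CRE.

An energy matrix assigns each (position, base) pair an additive
contribution (kT) to a protein's binding free energy over its footprint
within the cis-regulatory element; larger energy means weaker binding.
Mutation effects (p, r) on the RNAP-like and repressor-like proteins are
the energy differences between mutant and wildtype sequence under the two
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .thermo import MutationEffect

__all__ = [
    "BASES",
    "EnergyMatrix",
    "Mutation",
    "Genotype",
    "PanelResult",
    "sequence_energy",
    "mutation_effects",
    "reduce_spacer_position",
    "enumerate_single_mutations",
    "design_sign_category_panel",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SIGN_ZERO_TOL = 1e-9  # |effect| below this counts as no effect on that protein


@dataclass(frozen=True)
class EnergyMatrix:
    """Per-position, per-base binding-energy contributions (kT).

    ``entries`` has shape (length, 4) in base order A, C, G, T.
    ``reference_sequence`` is the bound sequence the matrix is anchored to
    and ``offset`` its 0-based start within the CRE (half-open footprint
    ``[offset, offset + length)`` on the sense strand).
    """

    name: str
    entries: np.ndarray
    reference_sequence: str
    offset: int = 0

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2 or entries.shape[1] != 4:
            raise ValueError(f"entries must have shape (length, 4), got {entries.shape}")
        if not np.all(np.isfinite(entries)):
            raise ValueError("energy-matrix entries must be finite")
        if len(self.reference_sequence) != entries.shape[0]:
            raise ValueError(
                f"reference_sequence length {len(self.reference_sequence)} != "
                f"matrix length {entries.shape[0]}"
            )
        if any(b not in _BASE_INDEX for b in self.reference_sequence):
            raise ValueError("reference_sequence must contain only A/C/G/T")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnergyMatrix):
            return NotImplemented
        return (
            self.name == other.name
            and self.offset == other.offset
            and self.reference_sequence == other.reference_sequence
            and np.array_equal(self.entries, other.entries)
        )

    @property
    def length(self) -> int:
        return self.entries.shape[0]

    @property
    def end(self) -> int:
        return self.offset + self.length

    def covers(self, position: int) -> bool:
        return self.offset <= position < self.end


@dataclass(frozen=True, order=True)
class Mutation:
    """A point substitution within the CRE (0-based position, sense strand)."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        for b in (self.ref, self.alt):
            if b not in _BASE_INDEX:
                raise ValueError(f"bases must be one of {BASES}, got {b!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt bases must differ")

    @property
    def label(self) -> str:
        """Standard 1-based substitution label, e.g. ``G12T``."""
        return f"{self.ref}{self.position + 1}{self.alt}"


@dataclass(frozen=True)
class Genotype:
    """Wildtype (no mutations), single or double mutant of the CRE."""

    id: str
    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        mutations = tuple(sorted(self.mutations))
        object.__setattr__(self, "mutations", mutations)
        positions = [m.position for m in mutations]
        if len(set(positions)) != len(positions):
            raise ValueError(f"genotype {self.id!r}: mutation positions must be distinct")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def validate_against(self, wt_seq: str) -> None:
        for m in self.mutations:
            if m.position >= len(wt_seq):
                raise ValueError(
                    f"genotype {self.id!r}: position {m.position} outside CRE of length {len(wt_seq)}"
                )
            if wt_seq[m.position] != m.ref:
                raise ValueError(
                    f"genotype {self.id!r}: ref base {m.ref} at position {m.position} "
                    f"does not match wildtype base {wt_seq[m.position]}"
                )

    def apply(self, wt_seq: str) -> str:
        self.validate_against(wt_seq)
        seq = list(wt_seq)
        for m in self.mutations:
            seq[m.position] = m.alt
        return "".join(seq)


def _seq_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"sequence contains a non-ACGT character: {exc.args[0]!r}") from None


def sequence_energy(seq: str, matrix: EnergyMatrix) -> float:
    """Binding energy (kT) of ``seq``'s footprint slice under ``matrix``.

    Positions contribute additively; ``seq`` is the full CRE and must cover
    the matrix footprint.
    """
    if matrix.end > len(seq):
        raise ValueError(
            f"matrix footprint [{matrix.offset}, {matrix.end}) exceeds sequence length {len(seq)}"
        )
    idx = _seq_indices(seq[matrix.offset : matrix.end])
    return float(matrix.entries[np.arange(matrix.length), idx].sum())


def _delta(genotype: Genotype, matrix: EnergyMatrix) -> float:
    """Energy change of the genotype relative to the matrix reference frame.

    Only mutations inside the footprint contribute; additivity makes the
    double-mutant delta the exact sum of the single-mutant deltas.
    """
    d = 0.0
    for m in genotype.mutations:
        if matrix.covers(m.position):
            j = m.position - matrix.offset
            d += matrix.entries[j, _BASE_INDEX[m.alt]] - matrix.entries[j, _BASE_INDEX[m.ref]]
    return float(d)


def mutation_effects(
    genotype: Genotype,
    rnap: EnergyMatrix,
    repressor: EnergyMatrix,
    wt_seq: str,
) -> MutationEffect:
    """Effect (p, r) of a genotype on RNAP and repressor binding energies."""
    for matrix in (rnap, repressor):
        if matrix.end > len(wt_seq):
            raise ValueError(
                f"matrix {matrix.name!r} footprint exceeds CRE length {len(wt_seq)}"
            )
    genotype.validate_against(wt_seq)
    return MutationEffect(_delta(genotype, rnap), _delta(genotype, repressor))


def reduce_spacer_position(
    matrix: EnergyMatrix, spacer_interval: tuple[int, int]
) -> EnergyMatrix:
    """Remove the lowest-impact position within a spacer interval.

    ``spacer_interval`` is half-open in matrix-local coordinates. The
    impact of a position is the range (max - min) of its four entries —
    the most a single base change there can move the binding energy. Ties
    are broken toward the 5'-most position. Used when a matrix carries one
    more spacer position than the promoter it is applied to.
    """
    start, end = spacer_interval
    if not (0 <= start < end <= matrix.length):
        raise ValueError(
            f"spacer interval [{start}, {end}) must be non-empty and inside [0, {matrix.length})"
        )
    impact = matrix.entries[start:end].max(axis=1) - matrix.entries[start:end].min(axis=1)
    drop = start + int(np.argmin(impact))  # argmin returns the first (5'-most) minimum
    keep = np.ones(matrix.length, dtype=bool)
    keep[drop] = False
    return EnergyMatrix(
        name=matrix.name,
        entries=matrix.entries[keep].copy(),
        reference_sequence=matrix.reference_sequence[:drop] + matrix.reference_sequence[drop + 1 :],
        offset=matrix.offset,
    )


# ---------------------------------------------------------------------------
# Panel design by sign category

def _effect_sign(delta: float, tol: float = SIGN_ZERO_TOL) -> int:
    if delta > tol:
        return 1
    if delta < -tol:
        return -1
    return 0


def enumerate_single_mutations(
    rnap: EnergyMatrix, repressor: EnergyMatrix, wt_seq: str
) -> list[tuple[Mutation, MutationEffect]]:
    """All single substitutions in the CRE with their (p, r) effects."""
    out = []
    for pos, ref in enumerate(wt_seq):
        if ref not in _BASE_INDEX:
            raise ValueError(f"wildtype sequence has non-ACGT base {ref!r} at position {pos}")
        for alt in BASES:
            if alt == ref:
                continue
            mut = Mutation(pos, ref, alt)
            g = Genotype(mut.label, (mut,))
            out.append((mut, mutation_effects(g, rnap, repressor, wt_seq)))
    return out


@dataclass
class PanelResult:
    """Double-mutant panel grouped by sign category.

    ``panels`` maps each requested category (an unordered pair of
    (sign p, sign r) tuples) to the sampled double mutants; categories with
    no qualifying single-mutation pair are listed in ``infeasible``.
    """

    panels: dict[tuple[tuple[int, int], tuple[int, int]], list[Genotype]]
    infeasible: list[tuple[tuple[int, int], tuple[int, int]]]
    seed: int

    @property
    def genotypes(self) -> list[Genotype]:
        return [g for panel in self.panels.values() for g in panel]


def design_sign_category_panel(
    rnap: EnergyMatrix,
    repressor: EnergyMatrix,
    wt_seq: str,
    categories: Sequence[tuple[tuple[int, int], tuple[int, int]]],
    n_per_category: int = 5,
    seed: int = 0,
    sign_tol: float = SIGN_ZERO_TOL,
) -> PanelResult:
    """Sample double mutants whose single-mutation effect signs match each category.

    For each category — an unordered pair of (sign p, sign r) classes —
    qualifying pairs of single mutations at distinct positions are
    enumerated exhaustively and ``n_per_category`` of them drawn uniformly
    without replacement (seeded). Categories with no qualifying pair are
    flagged infeasible rather than raising: on a strong site, no point
    mutation may improve binding of both proteins at once.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    singles = enumerate_single_mutations(rnap, repressor, wt_seq)
    buckets: dict[tuple[int, int], list[Mutation]] = {}
    for mut, eff in singles:
        buckets.setdefault((_effect_sign(eff.p, sign_tol), _effect_sign(eff.r, sign_tol)), []).append(mut)

    rng = np.random.default_rng(seed)
    panels: dict[tuple[tuple[int, int], tuple[int, int]], list[Genotype]] = {}
    infeasible: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for category in categories:
        cat_a, cat_b = (tuple(category[0]), tuple(category[1]))
        if cat_a == cat_b:
            group = buckets.get(cat_a, [])
            pairs = [
                (group[i], group[j])
                for i in range(len(group))
                for j in range(i + 1, len(group))
                if group[i].position != group[j].position
            ]
        else:
            pairs = [
                (a, b)
                for a in buckets.get(cat_a, [])
                for b in buckets.get(cat_b, [])
                if a.position != b.position
            ]
        key = (cat_a, cat_b)
        if not pairs:
            infeasible.append(key)
            continue
        chosen = rng.choice(len(pairs), size=min(n_per_category, len(pairs)), replace=False)
        panels[key] = [
            Genotype("_".join(m.label for m in sorted(pair)), tuple(pair))
            for pair in (pairs[int(i)] for i in sorted(chosen))
        ]
    return PanelResult(panels=panels, infeasible=infeasible, seed=seed)
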