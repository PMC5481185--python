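"""Readers and writers for the pipeline's plain-text formats.

Energy matrices travel as TSV (``pos A C G T``, energies in kT) with a
JSON sidecar (``<path>.json``) holding name, offset and reference
sequence; genotypes as CSV with one row per mutation; the wildtype CRE as
FASTA; fluorescence and estimate tables as CSV. All readers validate
strictly and report offending line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .empirical import FLUOR_COLUMNS
from .matrices import BASES, EnergyMatrix, Genotype, Mutation

__all__ = [
    "read_energy_matrix",
    "write_energy_matrix",
    "read_fasta",
    "write_fasta",
    "read_genotypes",
    "write_genotypes",
    "read_fluorescence",
    "write_fluorescence",
    "read_estimates",
    "write_estimates",
    "read_json",
    "write_json",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_energy_matrix(path: str | Path, matrix: EnergyMatrix) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.entries, columns=list(BASES))
    df.insert(0, "pos", np.arange(matrix.length))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    _sidecar(path).write_text(
        json.dumps(
            {
                "name": matrix.name,
                "offset": matrix.offset,
                "reference_sequence": matrix.reference_sequence,
            },
            indent=2,
        )
        + "\n"
    )


def read_energy_matrix(path: str | Path) -> EnergyMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["pos", *BASES]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header must be {' '.join(expected)}, got {' '.join(df.columns)}")
    if not np.array_equal(df["pos"].to_numpy(), np.arange(len(df))):
        bad = int(np.flatnonzero(df["pos"].to_numpy() != np.arange(len(df)))[0]) + 2
        raise ValueError(f"{path}:{bad}: positions must run 0..L-1 without gaps")
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"{path}: missing sidecar metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    return EnergyMatrix(
        name=meta["name"],
        entries=df[list(BASES)].to_numpy(dtype=float),
        reference_sequence=meta["reference_sequence"],
        offset=int(meta["offset"]),
    )


def write_fasta(path: str | Path, seq: str, name: str = "CRE") -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"{path}: non-ACGT characters in sequence: {sorted(bad)}")
    return seq


def write_genotypes(path: str | Path, genotypes: Iterable[Genotype]) -> None:
    rows = []
    for g in genotypes:
        if not g.mutations:
            rows.append({"id": g.id, "position": "", "ref": "", "alt": ""})
        for m in g.mutations:
            rows.append({"id": g.id, "position": m.position, "ref": m.ref, "alt": m.alt})
    pd.DataFrame(rows, columns=["id", "position", "ref", "alt"]).to_csv(path, index=False)


def read_genotypes(path: str | Path, wt_seq: str) -> list[Genotype]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "ref": str, "alt": str})
    expected = ["id", "position", "ref", "alt"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header must be {','.join(expected)}")
    mutations: dict[str, list[Mutation]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = row.id
        if gid not in mutations:
            mutations[gid] = []
            order.append(gid)
        if pd.isna(row.position) or row.position == "":
            continue  # explicit wildtype row
        try:
            mut = Mutation(int(row.position), str(row.ref), str(row.alt))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: {exc}") from None
        if mut.position >= len(wt_seq):
            raise ValueError(f"{path}:{i}: position {mut.position} outside CRE of length {len(wt_seq)}")
        if wt_seq[mut.position] != mut.ref:
            raise ValueError(
                f"{path}:{i}: ref base {mut.ref} does not match wildtype base "
                f"{wt_seq[mut.position]} at position {mut.position}"
            )
        mutations[gid].append(mut)
    return [Genotype(gid, tuple(mutations[gid])) for gid in order]


def write_fluorescence(path: str | Path, fluor: pd.DataFrame) -> None:
    fluor.loc[:, list(FLUOR_COLUMNS)].to_csv(path, index=False)


def read_fluorescence(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in FLUOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["fluorescence"].isna().any():
        bad = int(df.index[df["fluorescence"].isna()][0]) + 2
        raise ValueError(f"{path}:{bad}: missing fluorescence value")
    if (df["fluorescence"] < 0).any():
        bad = int(df.index[df["fluorescence"] < 0][0]) + 2
        raise ValueError(f"{path}:{bad}: negative fluorescence value")
    return df


def write_estimates(path: str | Path, estimates: pd.DataFrame) -> None:
    estimates.to_csv(path, index=False)


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"double", "environment", "epsilon", "log_epsilon", "q", "significant", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
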