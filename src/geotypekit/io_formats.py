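"""Readers and writers for the external formats the pipeline touches.

FASTA parsing goes through Biopython; tabular data through pandas.  The two
in-package fixtures — the 41-strain allelic-profile table and the 11 MLST
primer pairs — are shipped as TSV under ``geotypekit/data`` with pinned
checksums and are loaded by :func:`load_table1_fixture` /
:func:`load_table3_fixture`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    EmptyInputError,
    FixtureError,
    MatrixValidationError,
    ParseError,
)
from .linkage_stats import MISSING, HaplotypeMatrix

#: Fixed locus order of the six-locus typing scheme; all profile tables,
#: haplotype matrices and fixtures use it.
LOCUS_ORDER = ("ALA1", "CDC19", "SAPT4", "GLN4", "PGI1", "PGM2")

_FIXTURE_SHA256 = {
    "table1_profiles.tsv": "773022ec8fd219c678f8ffd4d9d52e7ed87a10e1b6f5053ade10398c0ff7c635",
    "table3_primers.tsv": "4e13b98a17d7488f2d0deef29f3f0820401d4a9de77f15e27840e9183c14a228",
}


@dataclass(frozen=True)
class StrainRecord:
    """One row of the strain table: identity, cluster labels, origin."""

    strain_id: str
    geo_complex: str  # "A", "B", "C" or "unknown"
    lineage: Optional[int]  # 1-5, or None when unknown
    st: Optional[int]  # sequence type, >= 1, or None when unassigned
    origin: str = ""

    def __post_init__(self):
        if self.st is not None and self.st < 1:
            raise ValueError(f"ST must be >= 1, got {self.st}")


@dataclass(frozen=True)
class PrimerPair:
    """A locus PCR primer pair with its expected product size."""

    locus: str
    forward: str
    reverse: str
    locus_size: int
    scheme: str = ""
    mlst2019: bool = False

    def __post_init__(self):
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{self.locus} {name} primer must be non-empty A/C/G/T")
        if self.locus_size <= 0:
            raise ValueError(f"{self.locus} locus_size must be positive")


def strain_key(label: str) -> str:
    """Comparison key for strain labels: the 'LMA-' prefix is optional."""
    s = str(label).strip()
    if s.upper().startswith("LMA-"):
        s = s[4:]
    return s


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into an ordered list of (id, sequence).

    Sequences are uppercased; IUPAC ambiguity letters are preserved.  An
    empty file raises :class:`EmptyInputError`; a header without sequence
    raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    empty = {rid for rid, seq in records if not seq}
    if empty:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if line.startswith(">") and line[1:].split()[0] in empty:
                    raise ParseError(f"{path}:{lineno}: header without sequence")
        raise ParseError(f"{path}: header without sequence")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def filter_scaffolds(
    records: list[tuple[str, str]], min_length: int = 1000
) -> list[tuple[str, str]]:
    """Keep scaffolds of length >= ``min_length`` (inclusive), order preserved.

    The default mirrors the 1,000 bp cut-off applied to draft assemblies
    before any k-mer comparison.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return [(rid, seq) for rid, seq in records if len(seq) >= min_length]


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

def read_profile_table(path) -> tuple[HaplotypeMatrix, list[StrainRecord]]:
    """Read a strain x locus allelic-profile TSV.

    Expected columns: ``strain`` plus the six loci of :data:`LOCUS_ORDER`;
    optional ``geo_complex``, ``lineage``, ``st``, ``origin``.  Missing
    alleles are encoded as ``-``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path}: empty profile table")
    missing_cols = [c for c in ("strain", *LOCUS_ORDER) if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    if df["strain"].duplicated().any():
        dup = df["strain"][df["strain"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate strain id {dup!r}")

    alleles = np.empty((len(df), len(LOCUS_ORDER)), dtype=int)
    for j, locus in enumerate(LOCUS_ORDER):
        col = df[locus].astype(str).str.strip()
        alleles[:, j] = [MISSING if v == "-" else int(v) for v in col]
    matrix = HaplotypeMatrix(tuple(df["strain"]), LOCUS_ORDER, alleles)

    def _opt_int(row, col):
        if col not in df.columns:
            return None
        v = str(row[col]).strip()
        return None if v in ("", "-", "nan", "unknown") else int(v)

    strains = [
        StrainRecord(
            strain_id=str(row["strain"]),
            geo_complex=str(row.get("geo_complex", "unknown")).strip() or "unknown",
            lineage=_opt_int(row, "lineage"),
            st=_opt_int(row, "st"),
            origin=str(row.get("origin", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    return matrix, strains


def write_profile_table(path, matrix: HaplotypeMatrix, strains=None) -> None:
    strains = {s.strain_id: s for s in (strains or [])}
    rows = []
    for i, sid in enumerate(matrix.strain_ids):
        rec = strains.get(sid)
        row = {
            "strain": sid,
            "geo_complex": rec.geo_complex if rec else "unknown",
            "lineage": rec.lineage if rec and rec.lineage is not None else "-",
            "st": rec.st if rec and rec.st is not None else "-",
        }
        for j, locus in enumerate(matrix.loci):
            a = int(matrix.alleles[i, j])
            row[locus] = "-" if a == MISSING else a
        row["origin"] = rec.origin if rec else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    ref = resources.files("geotypekit.data") / name
    digest = hashlib.sha256(ref.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(f"fixture {name} failed its pinned checksum")
    return ref


def load_table1_fixture() -> tuple[HaplotypeMatrix, list[StrainRecord]]:
    """The packaged 41-strain, six-locus allelic-profile table.

    Invariants checked on every load: 41 strains, 15 distinct STs, Geo
    complex counts A=31, B=6, C=4.
    """
    with resources.as_file(_fixture_path("table1_profiles.tsv")) as p:
        matrix, strains = read_profile_table(p)
    if matrix.n != 41:
        raise FixtureError(f"expected 41 strains, found {matrix.n}")
    sts = {s.st for s in strains}
    if len(sts) != 15:
        raise FixtureError(f"expected 15 distinct STs, found {len(sts)}")
    counts = pd.Series([s.geo_complex for s in strains]).value_counts().to_dict()
    if counts != {"A": 31, "B": 6, "C": 4}:
        raise FixtureError(f"unexpected Geo complex counts {counts}")
    return matrix, strains


def load_table3_fixture() -> list[PrimerPair]:
    """The packaged 11 MLST primer pairs; the six-locus 2019 subset is flagged."""
    with resources.as_file(_fixture_path("table3_primers.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    pairs = [
        PrimerPair(
            locus=row["locus"],
            forward=row["forward"],
            reverse=row["reverse"],
            locus_size=int(row["locus_size"]),
            scheme=row["scheme"],
            mlst2019=row["mlst2019"] == "1",
        )
        for _, row in df.iterrows()
    ]
    if len(pairs) != 11:
        raise FixtureError(f"expected 11 primer pairs, found {len(pairs)}")
    flagged = {p.locus for p in pairs if p.mlst2019}
    if flagged != set(LOCUS_ORDER):
        raise FixtureError(f"unexpected six-locus subset {sorted(flagged)}")
    return pairs


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------

def write_phylip_square(path, ids, values: np.ndarray) -> None:
    """Write a symmetric matrix in the square PHYLIP dialect."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as out:
        out.write(f"{len(ids)}\n")
        for i, rid in enumerate(ids):
            row = " ".join(f"{v:.10g}" for v in values[i])
            out.write(f"{rid:<12s}{row}\n")


def read_phylip_square(path) -> tuple[list[str], np.ndarray]:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty matrix file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"{path}:1: expected taxon count") from exc
    if len(lines) != n + 1:
        raise ParseError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(f"{path}:{lineno}: expected 1 label + {n} values")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    values = np.array(rows)
    if not np.allclose(values, values.T):
        raise MatrixValidationError(f"{path}: matrix is not symmetric")
    return ids, values
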