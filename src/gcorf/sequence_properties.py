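"""Per-protein sequence properties.

Computes, for each protein: the GC content of its coding sequence, its
amino-acid frequency vector, and its average score on each propensity scale.
Externally predicted properties (disorder, transmembrane or secondary
structure fractions produced by third-party predictors) are consumed as
precomputed per-protein tables and joined by identifier; the predictors
themselves are out of scope.

Conventions: the GC denominator excludes ambiguous bases (N etc.);
non-standard amino acids (X, B, Z, U, ...) are excluded from both scale
averages and frequency denominators, with counts logged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import AMINO_ACIDS
from .scales import BUILTIN_SCALES, PropensityScale

logger = logging.getLogger(__name__)

AGE_GROUPS = ("orphan", "genus_orphan", "intermediate", "ancient")

#: Fraction of ambiguous bases above which a CDS is flagged in the log.
AMBIGUITY_FLAG_THRESHOLD = 0.10


@dataclass
class ProteinRecord:
    """A protein with its species, optional CDS-derived GC and age group."""

    id: str
    species: str
    aa_sequence: str
    cds_gc: float | None = None
    age_group: str | None = None

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")


def gc_content(sequence: str) -> float:
    """GC fraction of a nucleotide sequence.

    Ambiguous bases (anything outside ACGT, e.g. N) are excluded from the
    denominator; sequences with more than 10% ambiguity are logged.

    Raises
    ------
    ValueError
        On an empty or all-ambiguous sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = Counter(seq)
    unambiguous = sum(counts[b] for b in "ACGT")
    if unambiguous == 0:
        raise ValueError("sequence contains no unambiguous bases")
    ambiguous = len(seq) - unambiguous
    if ambiguous / len(seq) > AMBIGUITY_FLAG_THRESHOLD:
        logger.warning(
            "sequence has %.0f%% ambiguous bases", 100 * ambiguous / len(seq)
        )
    return (counts["G"] + counts["C"]) / unambiguous


def _standard_residues(sequence: str) -> tuple[Counter, int]:
    counts = Counter(sequence.upper())
    dropped = sum(n for aa, n in counts.items() if aa not in AMINO_ACIDS)
    if dropped:
        logger.debug("dropped %d non-standard residues", dropped)
    return counts, dropped


def scale_average(sequence: str, scale: PropensityScale) -> float:
    """Mean propensity of a protein on a scale (composition-only statistic)."""
    counts, _ = _standard_residues(sequence)
    total = 0.0
    n = 0
    for aa in AMINO_ACIDS:
        c = counts.get(aa, 0)
        total += c * scale[aa]
        n += c
    if n == 0:
        raise ValueError("no standard residues left after filtering")
    return total / n


def aa_frequencies(sequence: str) -> np.ndarray:
    """Normalized amino-acid frequencies in :data:`AMINO_ACIDS` order."""
    counts, _ = _standard_residues(sequence)
    v = np.array([counts.get(a, 0) for a in AMINO_ACIDS], dtype=float)
    total = v.sum()
    if total == 0:
        raise ValueError("no standard residues in sequence")
    return v / total


def read_proteome_fasta(path: str | Path, species: str) -> list[ProteinRecord]:
    """Read a protein FASTA into records; the id is the first header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, species=species, aa_sequence=str(rec.seq))
        )
    return records


def attach_cds_gc(
    proteins: Sequence[ProteinRecord], cds_path: str | Path
) -> list[ProteinRecord]:
    """Attach per-gene GC from a CDS FASTA, pairing by identical id token.

    Length inconsistencies between CDS and protein (expected 3×(len+1)) are
    logged, not rejected: real annotations violate the relation routinely.
    Proteins without a matching CDS keep ``cds_gc=None``.
    """
    cds = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_path), "fasta")}
    matched = 0
    for prot in proteins:
        seq = cds.get(prot.id)
        if seq is None:
            continue
        if len(seq) != 3 * (len(prot.aa_sequence) + 1):
            logger.debug(
                "CDS/protein length mismatch for %s: %d nt vs %d aa",
                prot.id, len(seq), len(prot.aa_sequence),
            )
        prot.cds_gc = gc_content(seq)
        matched += 1
    logger.info("attached CDS GC for %d/%d proteins", matched, len(proteins))
    return list(proteins)


def load_external_properties(path: str | Path) -> pd.DataFrame:
    """Load externally predicted per-protein properties from TSV.

    The table must have an ``id`` column; every other column is numeric and
    interpreted as a fraction in [0, 1] (e.g. fraction of residues predicted
    disordered).

    Raises
    ------
    ValueError
        On a malformed numeric entry (with its line number) or an
        out-of-range fraction.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    out = df.set_index("id")
    for col in out.columns:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}:{lineno}: malformed numeric value "
                f"{out[col][bad].iloc[0]!r} in column {col!r}"
            )
        if ((parsed < 0) | (parsed > 1)).any():
            raise ValueError(
                f"{path}: column {col!r} has values outside [0, 1]"
            )
        out[col] = parsed
    return out


def build_property_table(
    proteins: Iterable[ProteinRecord],
    scales: Mapping[str, PropensityScale] = BUILTIN_SCALES,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per protein: id, species, age group, CDS GC, scale averages,
    the 20 amino-acid frequencies (``freq_A`` ... ``freq_Y``) and any
    external predictor columns.

    External rows whose id is absent from the proteome are skipped with a
    warning.
    """
    rows = []
    for prot in proteins:
        row: dict[str, object] = {
            "id": prot.id,
            "species": prot.species,
            "age_group": prot.age_group,
            "cds_gc": prot.cds_gc,
            "length": len(prot.aa_sequence),
        }
        for name, scale in scales.items():
            row[name] = scale_average(prot.aa_sequence, scale)
        for aa, f in zip(AMINO_ACIDS, aa_frequencies(prot.aa_sequence)):
            row[f"freq_{aa}"] = f
        rows.append(row)
    table = pd.DataFrame(rows).set_index("id")
    if external is not None:
        unknown = external.index.difference(table.index)
        if len(unknown):
            logger.warning(
                "%d external property rows have no matching protein "
                "(e.g. %s); skipped", len(unknown), unknown[0],
            )
        table = table.join(external.loc[external.index.intersection(table.index)])
    return table
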