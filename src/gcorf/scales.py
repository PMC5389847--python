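"""Amino-acid propensity scales.

A propensity scale maps each of the 20 standard amino acids to a real value;
a protein's score on a scale is the mean over its residues, so the score is a
pure function of amino-acid composition.

Six scales are built in:

``top_idp``
    Disorder-promoting propensity (Campen et al., 2008).  Higher values mean
    the residue is more common in intrinsically disordered regions.
``hydrophobicity``
    The biological (translocon-based) hydrophobicity scale of Hessa et al.
    (2005), expressed as apparent free energy of membrane insertion in
    kcal/mol; hydrophobic residues have *negative* values.
``helix``, ``sheet``, ``turn``
    Structure-derived normalized conformational frequencies of Palau,
    Argos & Puigdomenech (1981); values near 1 are indifferent, above 1
    favoured.
``coil``
    Normalized coil (aperiodic) frequency of Nagano (1973).

User-supplied scales can be loaded from a two-column TSV (amino acid, value).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .genetic_code import AMINO_ACIDS


@dataclass(frozen=True)
class PropensityScale:
    """A named mapping from the 20 standard amino acids to real propensities."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard amino "
                f"acids (missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def as_vector(self, order: tuple[str, ...] = AMINO_ACIDS) -> np.ndarray:
        """Scale values as a float array in the given amino-acid order."""
        return np.array([self.values[a] for a in order], dtype=float)

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


def _scale(name: str, spec: str) -> PropensityScale:
    values = {}
    for item in spec.split():
        aa, v = item.split(":")
        values[aa] = float(v)
    return PropensityScale(name=name, values=values)


# Campen et al. (2008), TOP-IDP.
TOP_IDP = _scale(
    "top_idp",
    "A:0.06 R:0.180 N:0.007 D:0.192 C:0.02 Q:0.318 E:0.736 G:0.166 H:0.303 "
    "I:-0.486 L:-0.326 K:0.586 M:-0.397 F:-0.697 P:0.987 S:0.341 T:0.059 "
    "W:-0.884 Y:-0.510 V:-0.121",
)

# Hessa et al. (2005), apparent ΔG of translocon-mediated membrane insertion.
HYDROPHOBICITY = _scale(
    "hydrophobicity",
    "A:0.11 R:2.58 N:2.05 D:3.49 C:-0.13 Q:2.36 E:2.68 G:0.74 H:2.06 "
    "I:-0.60 L:-0.55 K:2.71 M:-0.10 F:-0.32 P:2.23 S:0.84 T:0.52 "
    "W:0.30 Y:0.68 V:-0.31",
)

# Palau, Argos & Puigdomenech (1981), normalized conformational frequencies.
HELIX = _scale(
    "helix",
    "A:1.32 R:1.04 N:0.74 D:0.97 C:0.70 Q:1.25 E:1.48 G:0.59 H:1.06 "
    "I:1.01 L:1.22 K:1.13 M:1.47 F:1.10 P:0.57 S:0.77 T:0.86 "
    "W:1.02 Y:0.72 V:1.05",
)
SHEET = _scale(
    "sheet",
    "A:0.90 R:0.75 N:0.82 D:0.75 C:1.12 Q:0.95 E:0.44 G:0.83 H:0.86 "
    "I:1.59 L:1.24 K:0.75 M:0.94 F:1.41 P:0.46 S:0.70 T:1.20 "
    "W:1.28 Y:1.45 V:1.73",
)
TURN = _scale(
    "turn",
    "A:0.65 R:0.93 N:1.45 D:1.47 C:1.43 Q:0.94 E:0.75 G:1.53 H:0.96 "
    "I:0.57 L:0.56 K:0.95 M:0.71 F:0.72 P:1.51 S:1.46 T:0.96 "
    "W:0.90 Y:1.12 V:0.55",
)

# Nagano (1973), normalized coil frequency.
COIL = _scale(
    "coil",
    "A:0.72 R:1.33 N:1.38 D:1.04 C:1.01 Q:0.81 E:0.75 G:1.35 H:0.76 "
    "I:0.80 L:0.63 K:0.84 M:0.62 F:0.58 P:1.43 S:1.34 T:1.03 "
    "W:0.87 Y:1.35 V:0.83",
)

BUILTIN_SCALES: Mapping[str, PropensityScale] = MappingProxyType(
    {
        s.name: s
        for s in (TOP_IDP, HYDROPHOBICITY, HELIX, SHEET, COIL, TURN)
    }
)


def load_scale_tsv(path: str | Path, name: str | None = None) -> PropensityScale:
    """Load a propensity scale from a two-column TSV.

    The file must have exactly one row per standard amino acid (20 rows);
    a single header line is tolerated.  Column 1 is the one-letter amino
    acid, column 2 the propensity.
    """
    path = Path(path)
    rows: list[tuple[str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            aa, raw = fields
            if lineno == 1 and aa.upper() not in AMINO_ACIDS:
                continue  # header
            try:
                rows.append((aa.upper(), float(raw)))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {raw!r}"
                ) from None
    if len(rows) != 20:
        raise ValueError(f"{path}: expected 20 amino-acid rows, got {len(rows)}")
    return PropensityScale(name=name or path.stem, values=dict(rows))
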