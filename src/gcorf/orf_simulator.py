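"""Monte-Carlo generation of random ORFs at fixed GC content.

ORFs are built by drawing independent sense codons from the GC-conditioned
codon model, then adding an ATG start and a stop codon.  The default batch
design covers GC 20–90% in 1% steps with 400 ORFs per level, equally divided
among interior lengths of 300, 900, 1500 and 2100 bp (71 levels × 400 =
28,400 ORFs).  Realized GC and all downstream composition statistics are
computed on the randomly drawn interior codons only, so the fixed start and
stop codons do not bias short ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .codon_model import CodonModel
from .genetic_code import GeneticCode, standard_code

DEFAULT_LENGTHS_BP: tuple[int, ...] = (300, 900, 1500, 2100)


@dataclass(frozen=True)
class ORFRecord:
    """A single random open reading frame.

    ``sequence`` includes the ATG start and the stop codon; ``realized_gc``
    and ``interior_length_bp`` refer to the randomly drawn interior only.
    """

    sequence: str
    target_gc: float
    realized_gc: float
    interior_length_bp: int

    @property
    def interior(self) -> str:
        return self.sequence[3:-3]


@dataclass
class SimulationBatch:
    """A batch of random ORFs over a grid of GC levels."""

    gc_levels: list[float]
    n_per_level: int
    lengths_bp: list[int]
    seed: int
    orfs: list[ORFRecord] = field(default_factory=list)

    def by_level(self) -> dict[float, list[ORFRecord]]:
        out: dict[float, list[ORFRecord]] = {g: [] for g in self.gc_levels}
        for orf in self.orfs:
            out[orf.target_gc].append(orf)
        return out


def sample_codon(model: CodonModel, rng: np.random.Generator) -> str:
    """Draw one sense codon from the model's codon distribution."""
    probs = model.codon_probabilities()
    idx = rng.choice(len(probs), p=probs)
    return model.code.sense_codons[idx]


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def generate_orf(
    interior_length_bp: int, model: CodonModel, rng: np.random.Generator
) -> ORFRecord:
    """Generate one random ORF with the given interior length.

    The interior is ``interior_length_bp / 3`` sense codons drawn i.i.d.
    from the model; an ATG start and a uniformly chosen stop codon are then
    appended on top of the stated length.
    """
    if interior_length_bp <= 0 or interior_length_bp % 3:
        raise ValueError(
            f"interior_length_bp must be a positive multiple of 3, "
            f"got {interior_length_bp}"
        )
    n_codons = interior_length_bp // 3
    probs = model.codon_probabilities()
    sense = model.code.sense_codons
    idx = rng.choice(len(sense), size=n_codons, p=probs)
    interior = "".join(sense[i] for i in idx)
    stop = sorted(model.code.stop_codons)[rng.integers(3)]
    return ORFRecord(
        sequence=model.code.start_codon + interior + stop,
        target_gc=model.gc_freq,
        realized_gc=_gc_fraction(interior),
        interior_length_bp=interior_length_bp,
    )


def generate_batch(
    gc_min: float = 0.20,
    gc_max: float = 0.90,
    step: float = 0.01,
    n_per_level: int = 400,
    lengths_bp: Sequence[int] = DEFAULT_LENGTHS_BP,
    seed: int = 0,
    code: GeneticCode | None = None,
) -> SimulationBatch:
    """Generate a batch of random ORFs over a GC grid.

    The defaults follow the reference design: GC from 20% to 90% in steps of
    1%, 400 ORFs per level equally divided among interior lengths 300, 900,
    1500 and 2100 bp.  The batch is deterministic given ``seed``; each GC
    level draws from its own substream, so regenerating a single level
    reproduces the same ORFs.
    """
    if gc_min > gc_max:
        raise ValueError("gc_min must be <= gc_max")
    lengths_bp = list(lengths_bp)
    if n_per_level % len(lengths_bp):
        raise ValueError(
            f"n_per_level={n_per_level} not divisible by {len(lengths_bp)} lengths"
        )
    code = code or standard_code()
    n_levels = int(round((gc_max - gc_min) / step)) + 1
    levels = [round(gc_min + i * step, 10) for i in range(n_levels)]
    batch = SimulationBatch(
        gc_levels=levels,
        n_per_level=n_per_level,
        lengths_bp=lengths_bp,
        seed=seed,
    )
    per_length = n_per_level // len(lengths_bp)
    children = np.random.SeedSequence(seed).spawn(n_levels)
    for g, child in zip(levels, children):
        rng = np.random.default_rng(child)
        model = CodonModel(gc_freq=g, code=code)
        probs = model.codon_probabilities()
        sense = model.code.sense_codons
        stops = sorted(code.stop_codons)
        for length in lengths_bp:
            n_codons = length // 3
            idx = rng.choice(len(sense), size=(per_length, n_codons), p=probs)
            stop_idx = rng.integers(3, size=per_length)
            for row, si in zip(idx, stop_idx):
                interior = "".join(sense[i] for i in row)
                batch.orfs.append(
                    ORFRecord(
                        sequence=code.start_codon + interior + stops[si],
                        target_gc=g,
                        realized_gc=_gc_fraction(interior),
                        interior_length_bp=length,
                    )
                )
    return batch


def translate(orf: ORFRecord, code: GeneticCode | None = None) -> str:
    """Translate an ORF to its peptide (initiator Met included, stop excluded).

    Raises
    ------
    ValueError
        If the ORF contains an in-frame internal stop codon (a violated
        construction invariant).
    """
    code = code or standard_code()
    seq = orf.sequence
    if len(seq) % 3:
        raise ValueError("ORF length is not a multiple of 3")
    aas = []
    for i in range(0, len(seq) - 3, 3):
        aa = code.translate_codon(seq[i : i + 3])
        if aa == "*":
            raise ValueError(f"internal stop codon at position {i}")
        aas.append(aa)
    if code.translate_codon(seq[-3:]) != "*":
        raise ValueError("ORF does not end with a stop codon")
    return "".join(aas)


def interior_peptide(orf: ORFRecord, code: GeneticCode | None = None) -> str:
    """Peptide of the randomly drawn interior (no initiator Met, no stop)."""
    return translate(orf, code)[1:]


def write_batch_fasta(batch: SimulationBatch, path: str | Path) -> None:
    """Write a batch as nucleotide FASTA.

    Headers carry the target GC, interior length and replicate index:
    ``>orf_00000 target_gc=0.20 interior_bp=300 rep=0``.
    """
    with Path(path).open("w") as fh:
        reps: dict[tuple[float, int], int] = {}
        for i, orf in enumerate(batch.orfs):
            key = (orf.target_gc, orf.interior_length_bp)
            rep = reps.get(key, 0)
            reps[key] = rep + 1
            fh.write(
                f">orf_{i:05d} target_gc={orf.target_gc:g} "
                f"interior_bp={orf.interior_length_bp} rep={rep}\n"
            )
            fh.write(orf.sequence + "\n")


def read_batch_fasta(path: str | Path) -> list[ORFRecord]:
    """Read back ORFs written by :func:`write_batch_fasta`."""
    orfs: list[ORFRecord] = []
    header: dict[str, str] | None = None
    seq_parts: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(seq_parts)
        interior = seq[3:-3]
        orfs.append(
            ORFRecord(
                sequence=seq,
                target_gc=float(header["target_gc"]),
                realized_gc=_gc_fraction(interior),
                interior_length_bp=int(header["interior_bp"]),
            )
        )

    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                _flush()
                fields = dict(
                    kv.split("=") for kv in line[1:].split()[1:] if "=" in kv
                )
                header, seq_parts = fields, []
            elif line:
                seq_parts.append(line)
    _flush()
    return orfs


def interior_aa_counts(
    orfs: Iterable[ORFRecord], code: GeneticCode | None = None
) -> np.ndarray:
    """Pooled interior amino-acid counts over ORFs, in ``AMINO_ACIDS`` order."""
    from collections import Counter

    from .genetic_code import AMINO_ACIDS

    code = code or standard_code()
    pooled: Counter[str] = Counter()
    for orf in orfs:
        pooled.update(interior_peptide(orf, code))
    return np.array([pooled.get(a, 0) for a in AMINO_ACIDS], dtype=np.int64)
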