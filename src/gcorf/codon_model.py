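"""GC-conditioned codon model.

The model assigns each codon a weight that is the product over its three
positions of ``g`` for G/C nucleotides and ``1 - g`` for A/T nucleotides,
where ``g`` is the target GC frequency.  Normalizing the weights over the 61
sense codons yields the probability of drawing each codon in a random ORF at
that GC level.  Because the weights factorize over positions, the expected
amino-acid composition of a random protein at any GC content follows in
closed form by summing codon probabilities within each synonymous family.

At ``g = 0.5`` every sense codon is equally likely (1/61), so, for example,
a two-codon amino acid such as Glu is expected at 2/61 ≈ 3.3% of residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genetic_code import AMINO_ACIDS, BASES, GeneticCode, standard_code
from .scales import PropensityScale


def codon_weight(codon: str, g: float) -> float:
    """Unnormalized selection weight of ``codon`` at GC frequency ``g``.

    The weight is ``prod(g if base in "GC" else 1 - g)`` over the three
    codon positions.

    Raises
    ------
    ValueError
        If the codon is not a trinucleotide over ACGT.
    """
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}: expected 3 bases over ACGT")
    w = 1.0
    for b in codon:
        w *= g if b in "GC" else 1.0 - g
    return w


@dataclass(frozen=True)
class CodonModel:
    """The GC-conditioned distribution over the 61 sense codons.

    Parameters
    ----------
    gc_freq
        Target GC frequency ``g`` in [0, 1].
    code
        Genetic code; defaults to the standard code.
    """

    gc_freq: float
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_freq <= 1.0:
            raise ValueError(f"gc_freq must be in [0, 1], got {self.gc_freq}")

    def codon_distribution(self) -> dict[str, float]:
        """Probability of each sense codon, normalized to sum to 1."""
        probs = self.codon_probabilities()
        return dict(zip(self.code.sense_codons, probs))

    def codon_probabilities(self) -> np.ndarray:
        """Sense-codon probabilities as an array aligned with ``code.sense_codons``."""
        w = np.array(
            [codon_weight(c, self.gc_freq) for c in self.code.sense_codons]
        )
        return w / w.sum()

    def expected_aa_frequencies(self) -> dict[str, float]:
        """Expected amino-acid frequencies of a random protein at this GC.

        The frequency of an amino acid is the summed probability of its
        codons; the 20 values sum to 1 and are the analytic counterpart of
        the Monte-Carlo ORF simulator.
        """
        probs = self.codon_probabilities()
        freqs = dict.fromkeys(AMINO_ACIDS, 0.0)
        for codon, p in zip(self.code.sense_codons, probs):
            freqs[self.code.codon_to_aa[codon]] += p
        return freqs

    def expected_aa_vector(self) -> np.ndarray:
        """Expected amino-acid frequencies in :data:`AMINO_ACIDS` order."""
        f = self.expected_aa_frequencies()
        return np.array([f[a] for a in AMINO_ACIDS])


_CODE_ARRAYS: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _code_arrays(code: GeneticCode) -> tuple[np.ndarray, np.ndarray]:
    """Per-sense-codon GC counts and the 20×61 amino-acid indicator matrix."""
    key = id(code)
    if key not in _CODE_ARRAYS:
        ngc = np.array(
            [sum(b in "GC" for b in c) for c in code.sense_codons], dtype=float
        )
        aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        mat = np.zeros((20, len(code.sense_codons)))
        for j, c in enumerate(code.sense_codons):
            mat[aa_index[code.codon_to_aa[c]], j] = 1.0
        _CODE_ARRAYS[key] = (ngc, mat)
    return _CODE_ARRAYS[key]


def expected_aa_vector_fast(g: float, code: GeneticCode | None = None) -> np.ndarray:
    """Vectorized :meth:`CodonModel.expected_aa_vector` for tight loops."""
    code = code or standard_code()
    ngc, mat = _code_arrays(code)
    w = g**ngc * (1.0 - g) ** (3.0 - ngc)
    return mat @ (w / w.sum())


def expected_aa_curve(
    g_values: np.ndarray, code: GeneticCode | None = None
) -> np.ndarray:
    """Expected amino-acid frequencies over a grid of GC values.

    Returns an array of shape ``(len(g_values), 20)`` in :data:`AMINO_ACIDS`
    order.
    """
    code = code or standard_code()
    return np.array(
        [CodonModel(gc_freq=float(g), code=code).expected_aa_vector() for g in g_values]
    )


def mean_codon_gc(aa: str, code: GeneticCode | None = None) -> float:
    """Mean GC fraction of the codons encoding ``aa``.

    The mean is unweighted over the synonymous codons: each codon
    contributes (number of G/C among its three positions)/3.
    """
    code = code or standard_code()
    codons = code.codons_for(aa)
    return float(np.mean([sum(b in "GC" for b in c) / 3.0 for c in codons]))


def mean_codon_gc_vector(code: GeneticCode | None = None) -> np.ndarray:
    """Per-amino-acid mean codon GC in :data:`AMINO_ACIDS` order."""
    code = code or standard_code()
    return np.array([mean_codon_gc(a, code) for a in AMINO_ACIDS])


def scale_gc_correlation(
    scale: PropensityScale, code: GeneticCode | None = None
) -> float:
    """Pearson correlation, across the 20 amino acids, between mean codon GC
    and the scale value.

    This quantifies how strongly the genetic code couples GC content to the
    property the scale measures (e.g. disorder propensity).

    Raises
    ------
    ValueError
        If the scale is constant (correlation undefined).
    """
    code = code or standard_code()
    gc = mean_codon_gc_vector(code)
    v = scale.as_vector()
    if np.ptp(v) == 0.0:
        raise ValueError(f"scale {scale.name!r} is constant; correlation undefined")
    r, _ = stats.pearsonr(gc, v)
    return float(r)
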