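"""Codon model: GC-conditioned codon distribution and its analytic
amino-acid expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcorf import (
    AMINO_ACIDS,
    BUILTIN_SCALES,
    CodonModel,
    codon_weight,
    mean_codon_gc,
    mean_codon_gc_vector,
    scale_gc_correlation,
    standard_code,
)
from gcorf.codon_model import expected_aa_vector_fast
from gcorf.scales import PropensityScale


class TestGeneticCode:
    def test_standard_code_structure(self):
        code = standard_code()
        assert len(code.sense_codons) == 61
        assert code.stop_codons == {"TAA", "TAG", "TGA"}
        assert code.start_codon == "ATG"
        counts = {aa: len(code.codons_for(aa)) for aa in AMINO_ACIDS}
        assert all(c >= 1 for c in counts.values())
        assert sum(counts.values()) == 61

    def test_translate_codon(self):
        code = standard_code()
        assert code.translate_codon("ATG") == "M"
        assert code.translate_codon("TAA") == "*"
        with pytest.raises(ValueError):
            code.translate_codon("XYZ")


class TestCodonWeight:
    @pytest.mark.parametrize(
        "codon,g,expected",
        [("CCC", 0.6, 0.216), ("AAA", 0.6, 0.064), ("ATG", 0.5, 0.125)],
    )
    def test_examples(self, codon, g, expected):
        assert codon_weight(codon, g) == pytest.approx(expected)

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            codon_weight("ANG", 0.5)
        with pytest.raises(ValueError):
            codon_weight("AT", 0.5)


class TestCodonDistribution:
    def test_uniform_at_half(self):
        dist = CodonModel(0.5).codon_distribution()
        assert len(dist) == 61
        assert all(p == pytest.approx(1 / 61) for p in dist.values())

    def test_boundary_g1(self):
        dist = CodonModel(1.0).codon_distribution()
        support = {c for c, p in dist.items() if p > 0}
        assert support == {c for c in dist if set(c) <= set("GC")}
        assert len(support) == 8
        assert all(dist[c] == pytest.approx(1 / 8) for c in support)

    def test_boundary_g0_excludes_stop(self):
        dist = CodonModel(0.0).codon_distribution()
        support = {c for c, p in dist.items() if p > 0}
        assert len(support) == 7  # 8 all-A/T trinucleotides minus stop TAA
        assert "TAA" not in dist  # stop codons are not sense codons
        assert all(dist[c] == pytest.approx(1 / 7) for c in support)

    @pytest.mark.parametrize("g", np.linspace(0.0, 1.0, 11))
    def test_normalization_grid(self, g):
        probs = CodonModel(float(g)).codon_probabilities()
        assert probs.sum() == pytest.approx(1.0)
        assert (probs >= 0).all()

    def test_gc_freq_out_of_range(self):
        with pytest.raises(ValueError):
            CodonModel(1.2)


def brute_force_aa_frequencies(g: float) -> dict[str, float]:
    """Independent oracle: enumerate the 61 sense codons explicitly."""
    code = standard_code()
    weights = {}
    for codon in code.sense_codons:
        w = 1.0
        for b in codon:
            w *= g if b in "GC" else 1 - g
        weights[codon] = w
    z = sum(weights.values())
    freqs = dict.fromkeys(AMINO_ACIDS, 0.0)
    for codon, w in weights.items():
        freqs[code.codon_to_aa[codon]] += w / z
    return freqs


class TestExpectedAAFrequencies:
    def test_two_codon_aa_at_half(self):
        # Glu has 2 codons: expected 2/61 ~ 3.3% at 50% GC
        freqs = CodonModel(0.5).expected_aa_frequencies()
        assert freqs["E"] == pytest.approx(2 / 61)
        assert round(100 * freqs["E"], 1) == 3.3

    def test_proline_closed_form_at_040(self):
        # Pro codons are CCN: summed weight 2g^2 in units where the total
        # over 64 codons is 8; Z subtracts the three stop-codon weights.
        g = 0.4
        z = 8 - (1 - g) ** 3 - 2 * g * (1 - g) ** 2
        closed_form = 2 * g**2 / z
        freqs = CodonModel(g).expected_aa_frequencies()
        assert freqs["P"] == pytest.approx(closed_form, abs=1e-12)
        assert freqs["P"] < 0.05

    def test_boundary_g1(self):
        freqs = CodonModel(1.0).expected_aa_frequencies()
        for aa in "AGPR":
            assert freqs[aa] == pytest.approx(0.25)
        assert sum(v for a, v in freqs.items() if a not in "AGPR") == 0

    @pytest.mark.parametrize("g", [0.0, 0.1, 0.25, 0.4, 0.5, 0.63, 0.8, 1.0])
    def test_matches_enumeration_oracle(self, g):
        freqs = CodonModel(g).expected_aa_frequencies()
        oracle = brute_force_aa_frequencies(g)
        for aa in AMINO_ACIDS:
            assert freqs[aa] == pytest.approx(oracle[aa], abs=1e-12)
        fast = expected_aa_vector_fast(g)
        assert np.allclose(fast, [oracle[a] for a in AMINO_ACIDS], atol=1e-12)

    def test_monotone_aa_classes(self):
        grid = np.linspace(0.01, 0.99, 25)
        curves = {aa: [] for aa in AMINO_ACIDS}
        for g in grid:
            f = CodonModel(float(g)).expected_aa_frequencies()
            for aa in AMINO_ACIDS:
                curves[aa].append(f[aa])
        for aa in "PAG":  # high-GC amino acids rise with g
            assert np.all(np.diff(curves[aa]) > 0), aa
        for aa in "KFNYI":  # low-GC amino acids fall with g
            assert np.all(np.diff(curves[aa]) < 0), aa

    def test_complement_symmetry_of_weights(self):
        """Swapping A<->C and T<->G exchanges AT for GC content, so codon
        weights at g map onto complement-codon weights at 1-g exactly; the
        normalized sense-codon frequencies differ only through the
        stop-codon correction (checked via the normalizing constants)."""
        swap = str.maketrans("ACGT", "CATG")
        code = standard_code()
        for g in (0.2, 0.35, 0.5, 0.7):
            for codon in code.sense_codons:
                w = codon_weight(codon, g)
                w_c = codon_weight(codon.translate(swap), 1 - g)
                assert w == pytest.approx(w_c, abs=1e-15)
            # stop codons break the symmetry of the normalization
            z_g = sum(codon_weight(c, g) for c in code.sense_codons)
            z_c = sum(codon_weight(c, 1 - g) for c in code.sense_codons)
            stops_g = sum(codon_weight(c, g) for c in code.stop_codons)
            stops_c = sum(codon_weight(c, 1 - g) for c in code.stop_codons)
            assert z_g + stops_g == pytest.approx(z_c + stops_c)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_frequencies_sum_to_one(self, g):
        freqs = CodonModel(g).expected_aa_frequencies()
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in freqs.values())


class TestMeanCodonGC:
    @pytest.mark.parametrize(
        "aa,expected",
        [("P", 5 / 6), ("K", 1 / 6), ("I", 1 / 9)],
    )
    def test_examples(self, aa, expected):
        assert mean_codon_gc(aa) == pytest.approx(expected, abs=1e-4)

    def test_unknown_amino_acid(self):
        with pytest.raises(KeyError):
            mean_codon_gc("X")

    def test_high_and_low_gc_classes(self):
        gc = mean_codon_gc_vector()
        high = {a for a, v in zip(AMINO_ACIDS, gc) if v > 0.8}
        low = {a for a, v in zip(AMINO_ACIDS, gc) if v < 0.2}
        assert high == {"A", "G", "P"}
        assert low == {"K", "F", "N", "Y", "I"}


class TestScaleGCCorrelation:
    @pytest.mark.parametrize(
        "scale,expected",
        [("top_idp", 0.39), ("sheet", -0.42), ("hydrophobicity", 0.16)],
    )
    def test_printed_correlations(self, scale, expected):
        r = scale_gc_correlation(BUILTIN_SCALES[scale])
        assert round(r, 2) == expected

    def test_all_scales_within_reported_range(self):
        rs = [scale_gc_correlation(s) for s in BUILTIN_SCALES.values()]
        assert min(rs) == pytest.approx(-0.42, abs=0.005)
        assert max(rs) == pytest.approx(0.39, abs=0.005)

    def test_constant_scale_rejected(self):
        flat = PropensityScale("flat", {a: 1.0 for a in AMINO_ACIDS})
        with pytest.raises(ValueError):
            scale_gc_correlation(flat)
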