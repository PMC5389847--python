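"""Fully synthetic multi-species proteomes with known age structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can run — and be validated against planted truth —
without any database downloads:

* a rooted species tree (optionally with genus-level polytomies);
* per-species GC levels, and per-protein GC jittered around them
  (emulating within-genome GC variation);
* per-protein amino-acid composition drawn from
  ``(1 - λ) · E(g) + λ · π_ref``, where ``E(g)`` is the codon-model
  expectation at the protein's GC and ``π_ref`` a fixed reference
  composition — the dampening parameter ``λ`` grows with age, emulating
  selection gradually decoupling old proteins from the GC-driven
  composition of newborn ones;
* a coding sequence realized per residue by sampling synonymous codons with
  GC-conditioned weights, so protein composition and CDS GC are mutually
  consistent;
* an ortholog presence/absence matrix whose MRCA structure encodes each
  protein's intended age (orphans are singletons, kept out of the matrix).

Truth tables let round-trip tests check that age assignment recovers every
intended label.  Because intended ages are computed on the generator's own
polytomy resolution, round trips through a polytomous tree are exact when
age assignment resolves with the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import age_assignment
from .codon_model import expected_aa_vector_fast
from .genetic_code import AMINO_ACIDS, GeneticCode, standard_code
from .scales import BUILTIN_SCALES
from .sequence_properties import ProteinRecord

AGE_GROUPS = ("orphan", "genus_orphan", "intermediate", "ancient")

#: Age-group mixture matching the reported proportions in large eukaryote
#: panels (~0.8% orphans, ~0.6% genus orphans, ~15% intermediate, ~84%
#: ancient).
DEFAULT_MIXTURE = {
    "orphan": 0.008,
    "genus_orphan": 0.006,
    "intermediate": 0.15,
    "ancient": 0.836,
}

#: Mean protein lengths (aa) per age group, following the reported averages
#: (orphans ~100 aa rising to ~500 aa in ancient proteins).
DEFAULT_MEAN_LENGTH = {
    "orphan": 100,
    "genus_orphan": 150,
    "intermediate": 300,
    "ancient": 500,
}

#: Dampening per age group: newborn proteins track the GC-driven expectation
#: exactly (λ=0); older groups are pulled progressively toward π_ref.
DEFAULT_LAMBDA = {
    "orphan": 0.0,
    "genus_orphan": 0.25,
    "intermediate": 0.5,
    "ancient": 0.8,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A composition shift planted into one age group along a scale gradient."""

    age_group: str
    scale_name: str
    effect: float  # shift of the expected scale average, raw scale units


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic multi-species dataset.

    Species GC means are drawn from a normal distribution (default mean
    0.45, sd 0.08 — spanning roughly the yeast-to-*Drosophila* range of
    coding GC) and per-protein GC is jittered around the species level
    (sd 0.05, emulating isochore-scale variation).  Lengths are lognormal
    with age-group-specific means.
    """

    n_species: int = 16
    genus_size: int = 2
    n_polytomy_genera: int = 0  # genera given one extra species => polytomy
    n_proteins_per_species: int = 200
    species_gc_mean: float = 0.45
    species_gc_sd: float = 0.08
    protein_gc_sd: float = 0.05
    mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    dampening: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAMBDA)
    )
    mean_length: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_LENGTH)
    )
    length_sigma: float = 0.4  # lognormal sigma
    min_length: int = 30
    pi_ref: tuple[float, ...] | None = None  # default: E(g=0.5)
    emit_cds: bool = True
    planted: PlantedEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("age-group mixture must sum to 1")
        lam = [self.dampening[g] for g in AGE_GROUPS]
        if any(not 0.0 <= x <= 1.0 for x in lam):
            raise ValueError("dampening values must lie in [0, 1]")
        if not all(a <= b for a, b in zip(lam, lam[1:])):
            raise ValueError(
                "dampening must be non-decreasing with age "
                "(orphan <= genus <= intermediate <= ancient); "
                "construct with dataclasses.replace to override deliberately"
            )


def null_config(**overrides) -> SyntheticConfig:
    """A planted-null configuration: orphan and ancient proteins are drawn
    from identical distributions (equal dampening and lengths), so any
    per-species significant trend is a type-I error."""
    base = dict(
        mixture={
            "orphan": 0.4, "genus_orphan": 0.0,
            "intermediate": 0.0, "ancient": 0.6,
        },
        dampening={g: 0.5 for g in AGE_GROUPS},
        mean_length={g: 150 for g in AGE_GROUPS},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def plant_trend(
    config: SyntheticConfig,
    property_name: str,
    effect_size: float,
    age_group: str = "orphan",
) -> SyntheticConfig:
    """Return a config with one age group's composition shifted along a
    propensity-scale gradient.

    ``effect_size`` is the shift of the group's expected per-protein scale
    average, in raw scale units; 0 leaves the dataset unchanged (a null).
    """
    if property_name not in BUILTIN_SCALES:
        raise ValueError(f"unknown property {property_name!r}")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")
    return dataclasses.replace(
        config,
        planted=PlantedEffect(
            age_group=age_group, scale_name=property_name, effect=effect_size
        ),
    )


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    cds: dict[str, str]
    tree_newick: str
    matrix: pd.DataFrame
    membership: dict[str, str]
    truth: pd.DataFrame
    config: SyntheticConfig


def _species_names(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(n)]


def _build_tree_newick(config: SyntheticConfig) -> tuple[str, list[list[str]]]:
    """Group species into genera and join genus clades into a balanced tree.

    The first ``n_polytomy_genera`` genera get one extra species and are
    written as multifurcations.
    """
    names = _species_names(config.n_species)
    genera: list[list[str]] = []
    i = 0
    k = 0
    while i < len(names):
        size = config.genus_size + (1 if k < config.n_polytomy_genera else 0)
        genera.append(names[i : i + size])
        i += size
        k += 1
    if len(genera[-1]) < 2:
        raise ValueError(
            "last genus has a single species; choose n_species divisible by "
            "the genus layout"
        )
    clades = ["(" + ",".join(g) + ")" for g in genera]
    while len(clades) > 1:
        nxt = [
            f"({clades[j]},{clades[j + 1]})"
            for j in range(0, len(clades) - 1, 2)
        ]
        if len(clades) % 2:
            nxt.append(clades[-1])
        clades = nxt
    return clades[0] + ";", genera


def _ancestor_leafsets(tree, species: str) -> list[frozenset[str]]:
    """Leaf-label sets under each ancestor of ``species``: index a holds the
    clade of the ancestor ``a`` edges above the leaf."""
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    node = leaves[species]
    out = []
    while node.parent_node is not None:
        node = node.parent_node
        out.append(
            frozenset(l.taxon.label for l in node.leaf_iter())
        )
    return out


_FAMILY_CACHE: dict[int, dict[str, tuple[list[str], np.ndarray]]] = {}


def _codon_families(code: GeneticCode):
    key = id(code)
    if key not in _FAMILY_CACHE:
        fams = {}
        for aa in AMINO_ACIDS:
            codons = list(code.codons_for(aa))
            ngc = np.array([sum(b in "GC" for b in c) for c in codons], dtype=float)
            fams[aa] = (codons, ngc)
        _FAMILY_CACHE[key] = fams
    return _FAMILY_CACHE[key]


def _tilt_composition(p: np.ndarray, s: np.ndarray, effect: float) -> np.ndarray:
    """Exponentially tilt composition ``p`` along scale vector ``s`` so that
    the expected scale average shifts by ``effect``."""
    if effect == 0.0:
        return p
    s0 = s - s.mean()  # center for numerical stability
    base = float(p @ s)

    def shift(eta: float) -> float:
        w = p * np.exp(eta * s0)
        w /= w.sum()
        return float(w @ s) - base - effect

    eta = brentq(shift, -80.0, 80.0)
    w = p * np.exp(eta * s0)
    return w / w.sum()


def _sample_cds(
    aa_seq: str, g: float, code: GeneticCode, rng: np.random.Generator
) -> str:
    """Realize a CDS for ``aa_seq`` by sampling synonymous codons with
    GC-conditioned weights; ATG and a uniform stop codon are added."""
    fams = _codon_families(code)
    out = [None] * len(aa_seq)
    seq = np.frombuffer(aa_seq.encode(), dtype="S1")
    for aa in set(aa_seq):
        codons, ngc = fams[aa]
        w = g**ngc * (1.0 - g) ** (3.0 - ngc)
        total = w.sum()
        pos = np.flatnonzero(seq == aa.encode())
        if total == 0.0:  # g exactly 0 or 1 with no compatible codon
            idx = rng.integers(len(codons), size=pos.size)
        else:
            idx = rng.choice(len(codons), size=pos.size, p=w / total)
        for p_i, c_i in zip(pos, idx):
            out[p_i] = codons[c_i]
    stops = sorted(code.stop_codons)
    return code.start_codon + "".join(out) + stops[rng.integers(3)]


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a synthetic dataset; deterministic given ``config.seed``.

    Intended ages are realized as presence sets on the generator's own
    polytomy resolution of the emitted tree (resolution seed =
    ``config.seed``).  If ``out_dir`` is given, writes ``proteins.faa``,
    ``cds.fna``, ``tree.nwk``, ``orthogroups.tsv``, ``membership.tsv`` and
    ``truth.tsv``.
    """
    code = standard_code()
    newick, genera = _build_tree_newick(config)
    tree = age_assignment.read_tree(newick)
    resolved = age_assignment.resolve_polytomies(tree, seed=config.seed)
    depths = age_assignment.leaf_depths(resolved)
    species = _species_names(config.n_species)
    clades = {sp: _ancestor_leafsets(resolved, sp) for sp in species}

    pi_ref = (
        np.asarray(config.pi_ref, dtype=float)
        if config.pi_ref is not None
        else expected_aa_vector_fast(0.5, code)
    )
    if pi_ref.shape != (20,) or abs(pi_ref.sum() - 1.0) > 1e-9:
        raise ValueError("pi_ref must be a 20-vector summing to 1")

    groups = list(AGE_GROUPS)
    probs = np.array([config.mixture[g] for g in groups])
    planted = config.planted
    scale_vec = (
        BUILTIN_SCALES[planted.scale_name].as_vector() if planted else None
    )

    ss = np.random.SeedSequence(config.seed)
    sp_seed, prot_seed = ss.spawn(2)
    sp_rng = np.random.default_rng(sp_seed)
    species_gc = np.clip(
        sp_rng.normal(config.species_gc_mean, config.species_gc_sd,
                      size=config.n_species),
        0.25, 0.70,
    )

    proteins: list[ProteinRecord] = []
    cds: dict[str, str] = {}
    membership: dict[str, str] = {}
    matrix_rows: dict[str, frozenset[str]] = {}
    truth_rows = []

    for sp, gc_s, child in zip(
        species, species_gc, prot_seed.spawn(config.n_species)
    ):
        rng = np.random.default_rng(child)
        depth = depths[sp]
        ages_available = clades[sp]
        group_idx = rng.choice(len(groups), size=config.n_proteins_per_species,
                               p=probs)
        for j, gi in enumerate(group_idx):
            grp = groups[gi]
            pid = f"{sp}_p{j:04d}"
            if grp == "orphan":
                age = 0
            elif grp == "genus_orphan":
                age = 1
            elif grp == "ancient":
                age = depth
            else:
                if depth - 1 < 2:
                    raise ValueError(
                        "tree too shallow for intermediate ages; "
                        "increase n_species"
                    )
                age = int(rng.integers(2, depth))
            g_p = float(np.clip(rng.normal(gc_s, config.protein_gc_sd),
                                0.05, 0.95))
            lam = config.dampening[grp]
            comp = (1.0 - lam) * expected_aa_vector_fast(g_p, code) \
                + lam * pi_ref
            if planted is not None and grp == planted.age_group:
                comp = _tilt_composition(comp, scale_vec, planted.effect)
            length = max(
                config.min_length,
                int(round(rng.lognormal(
                    np.log(config.mean_length[grp]) - config.length_sigma**2 / 2,
                    config.length_sigma,
                ))),
            )
            body = "".join(
                np.array(AMINO_ACIDS)[rng.choice(20, size=length - 1, p=comp)]
            )
            aa_seq = "M" + body
            if config.emit_cds:
                cds[pid] = _sample_cds(body, g_p, code, rng)
            rec = ProteinRecord(
                id=pid, species=sp, aa_sequence=aa_seq,
                cds_gc=None, age_group=None,
            )
            proteins.append(rec)
            if grp != "orphan":
                gid = f"og_{pid}"
                membership[pid] = gid
                matrix_rows[gid] = ages_available[age - 1]
            truth_rows.append(
                {
                    "id": pid, "species": sp, "age_group": grp,
                    "age": age, "g_target": g_p, "dampening": lam,
                    "length": length,
                }
            )

    matrix = pd.DataFrame(
        [
            {sp: (sp in leaves) for sp in species} | {"group_id": gid}
            for gid, leaves in matrix_rows.items()
        ]
    )
    matrix = (
        matrix.set_index("group_id")
        if len(matrix)
        else pd.DataFrame(columns=species).rename_axis("group_id")
    )
    truth = pd.DataFrame(truth_rows).set_index("id")
    dataset = SyntheticDataset(
        proteins=proteins, cds=cds, tree_newick=newick, matrix=matrix,
        membership=membership, truth=truth, config=config,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "proteins.faa").open("w") as fh:
        for p in ds.proteins:
            fh.write(f">{p.id}\n{p.aa_sequence}\n")
    if ds.cds:
        with (out_dir / "cds.fna").open("w") as fh:
            for p in ds.proteins:
                if p.id in ds.cds:
                    fh.write(f">{p.id}\n{ds.cds[p.id]}\n")
    (out_dir / "tree.nwk").write_text(ds.tree_newick + "\n")
    age_assignment.write_ortholog_matrix(ds.matrix, out_dir / "orthogroups.tsv")
    pd.Series(ds.membership, name="group_id").rename_axis("id").to_csv(
        out_dir / "membership.tsv", sep="\t"
    )
    ds.truth.to_csv(out_dir / "truth.tsv", sep="\t")
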