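"""Phylogenetic age assignment for ortholog groups.

A protein family's gain is placed at the most recent common ancestor (MRCA)
of the species carrying it, under the assumption that a gain is far rarer
than a loss — so a single gain at the MRCA explains any presence/absence
pattern.  The age of a protein in a focal species is the number of edges
between the focal leaf and that MRCA on a strictly bifurcating tree; a
multifurcating input tree is first resolved to a random bifurcating topology
(deterministic given a seed).

Age groups:

* ``orphan`` — singleton, i.e. present in no ortholog group (age 0);
* ``genus_orphan`` — age 1 (configurable upper bound for lineages where
  strain-level taxa inflate the count, e.g. collapsed strain collections);
* ``ancient`` — age equal to the maximum age on the focal lineage (the
  root-level gain);
* ``intermediate`` — everything in between.

Note that species-specific (age-0) calls are invariant to how polytomies
are resolved; ages within a resolved polytomy are seed-dependent.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

AGE_GROUPS = ("orphan", "genus_orphan", "intermediate", "ancient")


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree from a file path or a newick string."""
    raw = str(source)
    text = raw if raw.lstrip().startswith("(") else Path(source).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"tree has duplicate leaf labels: {e}") from None
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree has duplicate leaf labels")
    return tree


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Return a copy of ``tree`` with every multifurcation randomly resolved.

    The output is strictly bifurcating, keeps the leaf set, and is
    deterministic given ``seed``.  An already-binary tree comes back
    topologically identical.
    """
    resolved = tree.clone(depth=1)
    resolved.is_rooted = True
    resolved.resolve_polytomies(rng=random.Random(seed))
    return resolved


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def leaf_depths(tree: dendropy.Tree) -> dict[str, int]:
    """Edge count from the root to each leaf (the maximum possible age)."""
    depths = {}
    for label, node in _leaf_map(tree).items():
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        depths[label] = d
    return depths


def assign_age(
    presence: Iterable[str], tree: dendropy.Tree, focal_species: str
) -> int:
    """Age of a protein of ``focal_species`` whose group spans ``presence``.

    The age is the number of edges between the focal leaf and the MRCA of
    the presence set; 0 means the group is confined to the focal species.

    Raises
    ------
    ValueError
        If the focal species is not in the presence set, or a species is
        not a leaf of the tree.
    """
    presence = set(presence)
    if focal_species not in presence:
        raise ValueError(
            f"focal species {focal_species!r} absent from presence set"
        )
    leaves = _leaf_map(tree)
    unknown = presence - set(leaves)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    if len(presence) == 1:
        return 0
    mrca = tree.mrca(taxon_labels=sorted(presence))
    node = leaves[focal_species]
    age = 0
    while node is not mrca:
        node = node.parent_node
        if node is None:
            raise RuntimeError("walked past the root looking for the MRCA")
        age += 1
    return age


def classify(
    age: int | None,
    is_singleton: bool,
    lineage_max_age: int,
    genus_max_age: int = 1,
) -> str:
    """Map an age to one of the four age groups.

    ``genus_max_age`` generalizes the strain-collapse special case: for
    lineages where strain-level taxa add one tree level below the genus,
    pass 2 so that genus-confined proteins are still called genus orphans.
    """
    if is_singleton:
        return "orphan"
    if age is None:
        raise ValueError("non-singleton protein needs an age")
    if age >= lineage_max_age:
        return "ancient"
    if 1 <= age <= genus_max_age:
        return "genus_orphan"
    return "intermediate"


@dataclass(frozen=True)
class AgeLabel:
    protein_id: str
    species: str
    age: int | None
    group: str


def read_ortholog_matrix(path: str | Path) -> pd.DataFrame:
    """Read a presence/absence matrix TSV: ``group_id`` column then one 0/1
    column per species."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("group_id")
    bad = df.index[(df.sum(axis=1) < 2)]
    if len(bad):
        raise ValueError(
            f"{path}: groups present in <2 species (e.g. {bad[0]!r}); "
            "singletons must be kept out of the matrix"
        )
    return df.astype(bool)


def write_ortholog_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).rename_axis("group_id").to_csv(path, sep="\t")


def assign_ages(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    membership: Mapping[str, str],
    species_of: Mapping[str, str],
    strain_collapsed_species: Iterable[str] = (),
    genus_max_age: int = 1,
) -> list[AgeLabel]:
    """Label every protein with its age and age group.

    Parameters
    ----------
    matrix
        Groups × species boolean presence matrix (groups in ≥2 species).
    tree
        A strictly bifurcating species tree (resolve polytomies first).
    membership
        Protein id → ortholog group id.  Proteins absent from the mapping
        are treated as singletons (orphans).
    species_of
        Protein id → species label.
    strain_collapsed_species
        Species whose genus orphans sit one level deeper because of
        strain-level taxa; they use ``genus_max_age + 1``.
    """
    depths = leaf_depths(tree)
    collapsed = set(strain_collapsed_species)
    presence_cache: dict[str, frozenset[str]] = {
        gid: frozenset(matrix.columns[row.to_numpy()])
        for gid, row in matrix.iterrows()
    }
    age_cache: dict[tuple[str, str], int] = {}
    labels = []
    for pid, sp in species_of.items():
        gid = membership.get(pid)
        if gid is None:
            labels.append(AgeLabel(pid, sp, None, "orphan"))
            continue
        key = (gid, sp)
        if key not in age_cache:
            age_cache[key] = assign_age(presence_cache[gid], tree, sp)
        age = age_cache[key]
        gmax = genus_max_age + 1 if sp in collapsed else genus_max_age
        labels.append(
            AgeLabel(pid, sp, age, classify(age, False, depths[sp], gmax))
        )
    return labels


def labels_to_frame(labels: Iterable[AgeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": l.protein_id,
                "species": l.species,
                "age": l.age,
                "age_group": l.group,
            }
            for l in labels
        ]
    ).set_index("id")
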