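"""End-to-end pipeline: ages → per-gene GC → properties → statistics.

``run_pipeline`` ties the stages together on file inputs and writes all
result tables plus a manifest of parameters under one output directory.
Proteins present in the proteome but absent from the ortholog membership are
treated as singletons (orphans) with a logged warning; the manifest records
this convention, since the upstream domain-based exclusion step that a real
orphan call would add is outside this package's scope.

All GC values are stored as fractions in [0, 1]; rendering as percentages is
left to presentation code.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import age_assignment, sequence_properties, stats_analysis
from .scales import BUILTIN_SCALES

logger = logging.getLogger(__name__)

SCALE_NAMES = tuple(BUILTIN_SCALES)


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters of one pipeline run."""

    proteome_fasta: Path
    cds_fasta: Path | None
    tree_path: Path
    matrix_path: Path
    membership_path: Path | None
    out_dir: Path
    external_properties: Path | None = None
    species_column_from_id: str = "_"  # id prefix up to first separator
    alpha: float = 0.01
    bin_width: float = 0.01
    min_count: int = 20
    seed: int = 0
    strain_collapsed_species: tuple[str, ...] = ()

    def validate(self) -> None:
        for p in (self.proteome_fasta, self.tree_path, self.matrix_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.cds_fasta, self.membership_path,
                  self.external_properties):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _species_from_id(pid: str, sep: str) -> str:
    return pid.split(sep, 1)[0]


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run all stages and write TSV outputs plus ``manifest.json``.

    Idempotent given the seed: rerunning the same config reproduces
    byte-identical tables.
    """
    config.validate()
    from Bio import SeqIO

    records = [
        sequence_properties.ProteinRecord(
            id=rec.id,
            species=_species_from_id(rec.id, config.species_column_from_id),
            aa_sequence=str(rec.seq),
        )
        for rec in SeqIO.parse(str(config.proteome_fasta), "fasta")
    ]
    if not records:
        raise ValueError(f"empty proteome: {config.proteome_fasta}")
    if config.cds_fasta is not None:
        sequence_properties.attach_cds_gc(records, config.cds_fasta)

    tree = age_assignment.read_tree(config.tree_path)
    resolved = age_assignment.resolve_polytomies(tree, seed=config.seed)
    matrix = age_assignment.read_ortholog_matrix(config.matrix_path)
    if config.membership_path is not None:
        membership = (
            pd.read_csv(config.membership_path, sep="\t", dtype=str)
            .set_index("id")["group_id"]
            .to_dict()
        )
    else:
        membership = {}
    n_singleton = sum(1 for r in records if r.id not in membership)
    if n_singleton:
        logger.warning(
            "%d proteins without ortholog-group membership treated as "
            "singletons (orphans)", n_singleton,
        )
    labels = age_assignment.assign_ages(
        matrix,
        resolved,
        membership,
        {r.id: r.species for r in records},
        strain_collapsed_species=config.strain_collapsed_species,
    )
    ages = age_assignment.labels_to_frame(labels)
    for rec in records:
        rec.age_group = ages.loc[rec.id, "age_group"]

    external = (
        sequence_properties.load_external_properties(config.external_properties)
        if config.external_properties is not None
        else None
    )
    properties = sequence_properties.build_property_table(
        records, external=external
    )

    trend = stats_analysis.species_trend_table(
        properties, list(SCALE_NAMES) + ["length"], alpha=config.alpha
    )

    reg_rows = []
    for prop in SCALE_NAMES:
        for grp, sub in properties.groupby("age_group"):
            try:
                res = stats_analysis.property_gc_regression(
                    sub["cds_gc"], sub[prop]
                )
            except ValueError:
                continue
            reg_rows.append(
                {
                    "property": prop, "age_group": grp,
                    "slope": res.slope, "intercept": res.intercept,
                    "r": res.r, "p_value": res.p_value,
                }
            )
    regressions = pd.DataFrame(reg_rows)

    curve_frames = []
    for prop in SCALE_NAMES:
        for grp, sub in properties.groupby("age_group"):
            curve = stats_analysis.running_average(
                sub["cds_gc"], sub[prop],
                bin_width=config.bin_width, min_count=config.min_count,
                property_name=prop, age_group=str(grp),
            )
            curve_frames.append(stats_analysis.curve_frame(curve))
    curves = pd.concat(curve_frames, ignore_index=True)

    aa_curves = stats_analysis.observed_vs_expected_aa(
        properties, bin_width=config.bin_width, min_count=config.min_count
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {
        "ages": ages,
        "properties": properties,
        "trend_table": trend,
        "regressions": regressions,
        "curves": curves,
        "aa_curves": aa_curves,
    }
    for name, frame in outputs.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t")
    manifest = {
        "gcorf_version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_proteins": len(records),
        "n_singletons": n_singleton,
        "caveat": (
            "proteins absent from the ortholog membership default to "
            "singleton/orphan status; no domain-based exclusion is applied"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outputs
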