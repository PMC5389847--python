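"""End-to-end pipeline on a synthetic multi-species dataset.

Generates a synthetic proteome panel in which young (orphan) proteins track
the GC-driven random composition exactly (dampening 0) while ancient
proteins are pulled 80% of the way toward a fixed reference composition,
then runs age assignment, property computation and the GC-regression stage,
and prints the fitted TOP-IDP-vs-GC slope per age group.  The orphan slope
should be markedly steeper — the signature of composition decoupling from
GC with evolutionary age.
"""

import tempfile
from pathlib import Path

from gcorf.pipeline import RunConfig, run_pipeline
from gcorf.synthetic_data import SyntheticConfig, generate_dataset

config = SyntheticConfig(
    n_species=8,
    n_proteins_per_species=120,
    mixture={"orphan": 0.4, "genus_orphan": 0.1,
             "intermediate": 0.1, "ancient": 0.4},
    dampening={"orphan": 0.0, "genus_orphan": 0.25,
               "intermediate": 0.5, "ancient": 0.8},
    seed=11,
)

with tempfile.TemporaryDirectory() as td:
    root = Path(td)
    generate_dataset(config, out_dir=root / "data")
    outputs = run_pipeline(
        RunConfig(
            proteome_fasta=root / "data/proteins.faa",
            cds_fasta=root / "data/cds.fna",
            tree_path=root / "data/tree.nwk",
            matrix_path=root / "data/orthogroups.tsv",
            membership_path=root / "data/membership.tsv",
            out_dir=root / "out",
            min_count=5,
            seed=config.seed,
        )
    )

ages = outputs["ages"]
print("age-group counts:")
print(ages["age_group"].value_counts().to_string(), "\n")

reg = outputs["regressions"]
top = reg[reg["property"] == "top_idp"].set_index("age_group")
print("TOP-IDP average vs per-protein GC (OLS):")
for grp in ("orphan", "genus_orphan", "intermediate", "ancient"):
    if grp in top.index:
        row = top.loc[grp]
        print(f"  {grp:13s} slope={row.slope:+.3f}  r={row.r:+.3f}  "
              f"p={row.p_value:.2e}")
print(
    "\nSlopes shrink with age: young proteins inherit the GC-driven random "
    "composition; older groups have drifted toward the reference composition."
)
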