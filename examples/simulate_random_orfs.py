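"""Monte-Carlo random ORFs versus the analytic expectation.

Generates a small batch of random ORFs on a GC grid, translates them, and
compares the mean disorder propensity (TOP-IDP average) per GC level with
the closed-form expectation from the codon model.  The two columns should
agree to a few thousandths — the simulator and the analytic model are two
routes to the same distribution.
"""

import numpy as np

from gcorf import BUILTIN_SCALES, generate_batch, scale_average, translate
from gcorf.codon_model import expected_aa_vector_fast

scale = BUILTIN_SCALES["top_idp"]
batch = generate_batch(
    gc_min=0.25, gc_max=0.65, step=0.10, n_per_level=80,
    lengths_bp=[900], seed=7,
)
print(f"{len(batch.orfs)} ORFs across {len(batch.gc_levels)} GC levels\n")
print("GC     simulated   expected")
for g, orfs in sorted(batch.by_level().items()):
    simulated = np.mean(
        [scale_average(translate(o)[1:], scale) for o in orfs]
    )
    expected = float(expected_aa_vector_fast(g) @ scale.as_vector())
    print(f"{g:.2f}   {simulated:+.4f}     {expected:+.4f}")
print(
    "\nMean disorder propensity of random proteins increases with GC: the "
    "genetic code maps GC-rich codons onto disorder-promoting residues."
)
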