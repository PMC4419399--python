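"""Assign secondary structure from coordinates and map it to a structural class.

Builds two synthetic chains — an alpha-helical one and a helix + paired-strand
composite — assigns H/E/C from backbone hydrogen bonds, and prints the CATH
and SCOP class labels with the helix/strand content that produced them.
"""

import numpy as np

from classfrag import synthetic
from classfrag.ss_class import (
    annotate_cath_class,
    annotate_scop_class,
    assign_secondary_structure,
    ss_content,
)
from classfrag.synthetic import SSSpec

# a mainly-alpha chain: two helices joined by a loop
helical = synthetic.make_ideal_structure(
    SSSpec([("C", 2), ("H", 12), ("C", 4), ("H", 10), ("C", 2)]),
    seed=1, structure_id="helical")

# an alpha+beta chain: a helix plus an antiparallel strand pair, placed apart
helix = synthetic.make_ideal_structure(SSSpec([("H", 12)]), seed=5)
helix = helix.transformed(np.eye(3), np.array([0.0, 60.0, 0.0]))
pair = synthetic.make_strand_pair(8, parallel=False, seed=2)
mixed = synthetic.concatenate_structures([helix, pair], structure_id="mixed")

for s in (helical, mixed):
    ss = assign_secondary_structure(s)
    h, e = ss_content(ss)
    cath = annotate_cath_class(h, e)
    scop = annotate_scop_class(s, ss)
    print(f"{s.id}: {ss.letters}")
    print(f"  helix {h:.2f}, strand {e:.2f} -> CATH {cath.label}, "
          f"SCOP {scop.label}")

# The content fractions drive the class call: >=15% helix with <10% strand is
# mainly-alpha; both above threshold is alpha-beta, split for SCOP into
# alpha+beta vs alpha/beta by sheet topology (parallel vs antiparallel).
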