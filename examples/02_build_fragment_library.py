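"""Build a class-constrained fragment library and measure how well it fits.

Generates a mixed-class template database and a mainly-alpha target, keeps
only high-resolution templates of the target's class (dropping homologs),
picks score-ranked 9-mer fragments per position, and reports the library's
fit against the target's true structure.
"""

import numpy as np

from classfrag import synthetic
from classfrag.fragment_picker import library_fit, pick_fragments, write_fragment_file
from classfrag.ss_class import annotate_cath_class, ss_content
from classfrag.template_select import filter_templates, find_homologs_by_identity

# synthetic study conditions: 5 alpha / 15 beta templates, 40-residue target
db, truth = synthetic.make_template_db({"mainly_alpha": 5, "mainly_beta": 15},
                                       lengths=(50, 80), seed=42)
rng = np.random.default_rng(7)
spec = synthetic.class_spec("mainly_alpha", 40, rng)
native = synthetic.make_ideal_structure(spec, seed=7, structure_id="target")
profile, ss_pred = synthetic.make_profile_and_ss(native.sequence, spec.letters,
                                                 sharpness=0.9, seed=7)

target_class = annotate_cath_class(*ss_content(spec.letters))
homologs = find_homologs_by_identity(native.sequence, db)
kept = filter_templates(db, target_class, max_resolution=2.5,
                        homologs=homologs, e_cut=0.05)
print(f"templates: {len(db)} loaded -> {len(kept)} after class/resolution/"
      f"homolog filters ({sorted(kept.ids)})")

library = pick_fragments(native.sequence, profile, ss_pred, kept,
                         length=9, n_frags=25)
write_fragment_file(library, "frags_9mers.txt")
fit = library_fit(library, native)
print(f"positions: {len(fit)}; mean best-fragment CA-RMSD: "
      f"{fit['best_rmsd'].mean():.2f} A; "
      f"mean fraction under 1 A: {fit['frac_under_1A'].mean():.2f}")

# best_rmsd near zero at helical positions means the library contains
# fragments nearly identical to the native local structure — the property
# that makes fragment assembly converge on the native fold.
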