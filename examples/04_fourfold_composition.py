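"""Base composition at four-fold degenerate synonymous sites.

Third positions of four-fold codon boxes change composition without
changing the protein, so their base frequencies read out mutational and
compositional pressure with protein-level selection largely removed.
"""

from virodisorder.composition import (
    base_composition,
    fourfold_codon_set,
    fourfold_site_composition,
)
from virodisorder.simulate import back_translate
import numpy as np

print("four-fold degenerate codon boxes:", sorted(fourfold_codon_set()))

# back-translate the same protein under two synonymous-site biases
rng = np.random.default_rng(0)
protein = "".join(rng.choice(list("APTVGRLSEKQ"), size=3000))

for label, bias in (("C-favouring", (0.15, 0.55, 0.15, 0.15)),
                    ("T-favouring", (0.15, 0.15, 0.15, 0.55))):
    cds = back_translate(protein, bias, np.random.default_rng(1))
    all_sites = base_composition(cds)
    ff = fourfold_site_composition([cds])
    print(f"\n{label} synonymous bias "
          f"({ff.n_sites} four-fold sites of {len(cds)} nt):")
    print(f"  all sites : A {all_sites.a:.3f}  C {all_sites.c:.3f}  "
          f"G {all_sites.g:.3f}  T {all_sites.t:.3f}")
    print(f"  four-fold : A {ff.a:.3f}  C {ff.c:.3f}  "
          f"G {ff.g:.3f}  T {ff.t:.3f}")
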