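"""Detect the 9-bp duplication signature of singly tagmented circles.

Builds a small library of 5% singly cut circles mixed into 95% linear
genomic fragments, then reports the per-sample signature fraction and its
fold enrichment over a purely linear control — the same statistics a real
experiment reports per library.
"""

import numpy as np

from ecckit import Molecule, TagmentationParams, signature_fold_enrichment, signature_fraction
from ecckit.simulate import _random_bases, fragments_to_read_pairs, tagment_circle

rng = np.random.default_rng(0)
params = TagmentationParams(read_length=100)


def library(n_pairs: int, circle_fraction: float) -> list:
    pairs = []
    for i in range(n_pairs):
        if rng.random() < circle_fraction:
            mol = Molecule(_random_bases(rng, 300, 0.5), "circular")
            frag = tagment_circle(mol, params, rng)[0]  # one cut: ends share 9 bp
        else:
            frag = Molecule(_random_bases(rng, 300, 0.5))  # interior fragment
        pairs.extend(fragments_to_read_pairs([frag], params, name_prefix=f"m{i}"))
    return pairs


enriched = signature_fraction(library(5000, circle_fraction=0.05))
control = signature_fraction(library(5000, circle_fraction=0.0005))
fold = signature_fold_enrichment(enriched, control)

print(f"enriched: {enriched.n_evidence}/{enriched.n_pairs} pairs "
      f"= {enriched.fraction:.3g}% carry the duplication")
print(f"control:  {control.n_evidence}/{control.n_pairs} pairs "
      f"= {control.fraction:.3g}%")
print(f"fold enrichment of singly tagmented circles: {fold:.1f}")
# The enriched fraction tracks the true circle proportion (5%); the fold is
# the library-level evidence that the sample is enriched for circular DNA.
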