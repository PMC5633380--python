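"""Direct-repeat excision: the Cre/loxP reference-circle construction.

A circular plasmid carrying a 378-bp spacer between two directly repeated
34-bp sites recombines into two circles.  The lengths printed (412 bp and
3034 bp for a 3000-bp backbone) are the expected reference-circle sizes
used to validate a circle-capture protocol.
"""

import numpy as np

from ecckit import Molecule, excise_between_direct_repeats
from ecckit.simulate import _random_bases

rng = np.random.default_rng(1)
backbone = _random_bases(rng, 3000, 0.5)
loxp = _random_bases(rng, 34, 0.5)
spacer = _random_bases(rng, 378, 0.5)

parent = Molecule(backbone + loxp + spacer + loxp, "circular")
circle, remainder = excise_between_direct_repeats(parent, 34, 3000, 3412)

print(f"parent plasmid: {len(parent)} bp (circular)")
print(f"excised circle: {len(circle)} bp  (spacer + one repeat copy)")
print(f"remaining parent: {len(remainder)} bp  (backbone + one repeat copy)")
# Length is conserved: each daughter circle keeps exactly one repeat copy.
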