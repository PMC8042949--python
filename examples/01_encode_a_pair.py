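"""Encode one protein pair into its SSC tensor and inspect the channels.

Uses the first twenty residues of the human CNKR1 protein as one partner,
showing the worked bigram asymmetry: M-E codes to 0.5075 but E-M to 0.1750,
which is what makes the context channel direction-sensitive.
"""

import numpy as np

from sscppi import (
    CNKR1_PREFIX,
    EncodingConfig,
    encode_bigram,
    encode_interaction,
    encode_residue,
)

partner = "GAVLIMFWPSTCYNQDEKRH" * 2  # a toy 40-residue partner

config = EncodingConfig()  # 1800 slots per protein, 60 x 60 grid, S1+S2+C
tensor = encode_interaction(CNKR1_PREFIX, partner, config, pair_ids=("CNKR1", "toy"))

print(f"tensor shape: {tensor.shape} channels {tensor.channel_order}")
print(f"S1[0] (code of M):         {tensor.flattened('S1')[0]:.4f}"
      f"  == encode_residue('M') = {encode_residue('M'):.4f}")
print(f"C[0]  (code of M-E):       {tensor.flattened('C')[0]:.4f}"
      f"  vs E-M = {encode_bigram('E', 'M'):.4f}  (ordered, so asymmetric)")

# Swapping the pair reverses the flattened S1/S2 layout exactly...
swapped = encode_interaction(partner, CNKR1_PREFIX, config)
print("S1 centrosymmetric under swap:",
      np.array_equal(tensor.flattened("S1")[::-1], swapped.flattened("S1")))
# ...but not the context channel, which encodes reading direction.
print("C breaks the symmetry:      ",
      not np.array_equal(tensor.flattened("C")[::-1], swapped.flattened("C")))
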