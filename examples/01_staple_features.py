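"""Staple-motif featurization of a DNA template sequence.

Counts all 144 gapped base-pair motifs X_mY (bases X and Y separated by
m = 0..8 arbitrary bases) in a 10-mer; every 10-mer contains exactly 45
staple occurrences.
"""

import numpy as np

from agndesign import feature_names, one_hot, staple_features

seq = "CACCGGTTGG"
v = staple_features(seq)
names = feature_names()

print(f"sequence        : {seq}")
print(f"feature vector  : length {v.size}, total count {v.sum()}")
top = np.argsort(v)[::-1][:5]
print("most frequent staples:")
for i in top:
    print(f"  {names[i]:>5} x {v[i]}")
print(f"one-hot length  : {one_hot(seq).size}")
# The staple counts say which base pairs, at which separations, are
# available to bridge surface silver atoms; G_0G / C_0C content is the
# main driver of nanocluster color.
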