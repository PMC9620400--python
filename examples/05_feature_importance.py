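"""Which staple motifs drive each color class? MISA and net importance.

Scores every staple feature against shuffled shadow copies for each class
pair (random-forest importance), then folds the pairwise scores into a
signed Net Importance Score per (feature, class).
"""

import numpy as np

from agndesign import (
    class_frequencies,
    default_rules,
    featurize,
    generate_dataset,
    net_importance,
    shadow_importance,
    top_features,
)
from agndesign.ensemble import class_pairs

ds = generate_dataset(default_rules(), n=3000, seed=5)
X, _ = featurize(ds.sequences)
y = np.array([l.value for l in ds.labels])

records = {}
for i, pair in enumerate(class_pairs()):
    mask = np.isin(y, [pair[0].value, pair[1].value])
    records[pair] = shadow_importance(
        X[mask], (y[mask] == pair[0].value).astype(int), pair, n_repeats=5, seed=10 + i
    )

nis = net_importance(records, class_frequencies(X, ds.labels))
print("top staple features by |NIS| (positive = favors the class):")
print(top_features(nis, 8).round(3).to_string())
# G_0G (adjacent guanines) should favor FarRed/NIR and disfavor
# Dark/Green/Red -- consecutive Gs template the larger, longer-wavelength
# silver clusters.
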