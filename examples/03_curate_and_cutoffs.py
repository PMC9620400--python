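"""Training-set curation rules and k-means wavelength cutoffs.

Labels a handful of sequence/peak rows (brightest-bright-peak rule, the
580-600 nm gap, multiclass and mediocre-brightness exclusions) and runs
the exact 1-D k-means that motivates the class boundaries.
"""

import numpy as np

from agndesign import curate_training, kmeans_cutoffs

rows = [
    ("CACCGGTTGG", [(630.0, 1.2)]),            # one bright Red peak
    ("CCCCAACCCC", [(545.0, 0.9), (560.0, 0.4)]),  # two Green peaks
    ("GGGGTTGGGG", [(640.0, 1.0), (850.0, 0.8)]),  # bright in two classes
    ("ATATATATAT", []),                         # no emission
    ("ACGTACGTAC", [(590.0, 1.5)]),             # brightest in the 580-600 gap
    ("TTGGAACCTT", [(700.0, 0.12)]),            # mediocre brightness
]
result = curate_training(rows)
for rec in result.labeled:
    print(f"  {rec.sequence} -> {rec.label.value}")
for seq, reason in result.exclusions:
    print(f"  {seq} -> excluded ({reason})")

# class cutoffs from clustering a pool of peak wavelengths
rng = np.random.default_rng(1)
lam = np.concatenate([rng.normal(c, 15, 200) for c in (545, 635, 690, 800)])
report = kmeans_cutoffs(lam, k=4)
print("k-means centroids (nm):", np.round(report.centroids, 1))
print("midpoints between them:", np.round(report.midpoints, 1))
# The midpoints are the natural class boundaries; with the experimental
# data pool they fall near the 592/662/742 nm values that justify the
# Green/Red and Red/FarRed cutoffs.
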