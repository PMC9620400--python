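# agndesign

Design DNA template sequences for DNA-stabilized silver nanoclusters
(Ag<sub>N</sub>-DNAs) with a target fluorescence color — including
near-infrared emitters for imaging in the tissue transparency windows.

Single-stranded DNA oligomers template few-atom silver nanoclusters whose
emission color is selected by the base sequence. Ten-base templates span a
space of 4¹⁰ = 1,048,576 sequences, of which only a fraction of a percent
has ever been synthesized, and bright NIR emitters (λ<sub>p</sub> > 800 nm)
are rare. `agndesign` implements a chemistry-informed machine-learning
pipeline that learns the sequence→color map from high-throughput well-plate
data and exhaustively screens the full sequence space for candidates:

1. **Spectral fitting** — emission spectra are fitted to sums of 1–3
   Gaussians in photon energy (`E = hc/λ`); each peak yields a wavelength
   λ<sub>p</sub> and a control-normalized brightness.
2. **Curation** — sequences are labeled Dark, Green (λ<sub>p</sub> < 580 nm),
   Red (600–660 nm), Far Red (660–800 nm) or NIR (> 800 nm) by their
   brightest bright peak; peaks in the 580–600 nm gap, multi-class
   emitters and mediocre-brightness products are excluded. Class cutoffs
   are backed by an exact (dynamic-programming) 1-D k-means on the pooled
   λ<sub>p</sub> values.
3. **Featurization** — a sequence is represented by the counts of all 144
   "staple" motifs X\_mY: ordered base pairs X, Y separated by m = 0…8
   arbitrary bases, the patterns by which two nucleobases bridge surface
   silver atoms in Ag<sub>N</sub>-DNA crystal structures.
4. **Classification** — an ensemble of 100 linear SVMs: for each of the
   C(5,2) = 10 class pairs, 10 L1-regularized classifiers (c = 0.1) are
   trained on different balanced subsamples of the majority class, which
   keeps the rare NIR class from being swamped (~10× fewer NIR than Far
   Red sequences). Pair probabilities are member-averaged logistic margins.
5. **Feature analysis** — Boruta-style shadow features: a feature is
   important for a class pair only if its random-forest importance beats
   the best randomly shuffled shadow copy (MISA); the four pairwise scores
   of a class combine into a signed Net Importance Score,
   NIS(f, c) = Σ<sub>o≠c</sub> sign(freq<sub>c</sub>(f) − freq<sub>o</sub>(f)) · MISA(f, {c,o}).
6. **Design** — every sequence is scored for a target class by the
   **minimum** of its four pairwise probabilities, so top candidates are
   unlikely to fall into *any* undesired class; the top 124 fill a
   384-well synthesis plate alongside controls.

A planted-rule synthetic data generator with the same statistical shape as
the experimental library (imbalanced classes, motif-driven labels,
class-consistent synthetic spectra) makes every stage testable end to end.

## Worked example

Train on 5,000 synthetic planted-rule sequences and screen the full 4¹⁰
space for NIR candidates (`examples/06_design_nir.py`):

```text
screened 1,048,576 sequences for target NIR
 rank   sequence  score  p_vs_Dark  p_vs_Green  p_vs_Red  p_vs_FarRed
    1 GGGGGGGGGG 0.9997     1.0000      0.9997    1.0000          1.0
    2 AGGGGGGGGG 0.9992     0.9999      0.9992    1.0000          1.0
    3 CGGGGGGGGG 0.9992     0.9999      0.9992    0.9999          1.0

top-124 sequences containing the GG staple: 100%
```

The score of a candidate is its worst pairwise NIR probability; the
G-rich winners reflect the planted rule that consecutive guanines
(G\_0G) template the larger, longer-wavelength clusters — the same motif
the importance analysis ranks first (`examples/05_feature_importance.py`):

```text
      max_abs_nis   Dark  Green    Red  FarRed    NIR
G_0G        0.546 -0.315 -0.413 -0.335   0.546  0.518
C_0C        0.444 -0.266  0.444 -0.188   0.158 -0.148
```

Positive NIS = the motif favors that class. The other examples cover
featurization (`01`), spectral fitting (`02`), curation and k-means
cutoffs (`03`), and ensemble training/cross-validation (`04`).

A thin CLI mirrors the stages:

```sh
agndesign run-all --seed 1 --out-dir out/          # full pipeline
agndesign design --target NIR --k 124 --model out/model.json
```

## Layout

```
src/agndesign/    features, spectra, curation, ensemble, importance,
                  design, synthetic, io, pipeline, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   models, assumptions, parameter choices, limitations
```
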