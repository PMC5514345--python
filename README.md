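# acetowhite

Temporal analysis of the acetowhitening reaction in digital colposcopy.

After 3–5% acetic acid is applied to the cervix, abnormal epithelium whitens
transiently. The *strength* of the whitening is a poor discriminator — benign
conditions (inflammation, ectopy, metaplasia) whiten too — but its *temporal
profile* carries diagnostic signal. This package implements the full analysis
chain for classifying cervical tissue from that profile:

1. **Registration** of the colposcopic frame sequence (10 baseline frames +
   180 post-acid frames at 1 frame/s, 352×240 px) by exhaustive integer-pixel
   normalized cross-correlation between consecutive frames.
2. **Extraction** of the acetowhite response function (Awrf): the mean
   grayscale intensity of a biopsy-matched region over time.
3. **Representations** of each Awrf *x(t)*: percent change relative to the
   pre-acid basal level, `100·(x_t − basal)/basal`; a least-squares fit of
   the whitening-kinetics polynomial
   `f(t) = θ₀ + θ₁√t + θ₂t + θ₃t² + θ₄t³` on scaled time *t* ∈ [0,1] (the
   fitted curve and the coefficient vector θ are two further
   representations); and two symbolic encodings over a variable-width
   segmentation — **PLA** (each segment's mean mapped to one of *a* alphabet
   intervals) and **PSA** (each segment's least-squares slope mapped to one
   of seven symbols {−3…3}).
4. A mutation-only **evolutionary program** that jointly searches segment
   boundaries (word sizes) and alphabet size, scoring each scheme by
   cross-validated accuracy of the downstream classifier.
5. From-scratch **k-nearest-neighbors, naive Bayes, and C4.5** classifiers
   (the WEKA IBk / NaiveBayes / J4.8 trio) emitting proper class-score
   distributions.
6. A WEKA-style **evaluation suite**: confusion matrices, per-class
   one-vs-rest TP/FP rate, precision, recall, F-measure, MCC, ROC and PRC
   areas, weighted averages, Wilson confidence intervals, and stratified
   k-fold cross-validation.

Because no public colposcopy sequence dataset exists, the package ships a
synthetic generator that reproduces the statistical structure the analysis
assumes — class-specific whitening kinetics, lighting noise and drift,
translational patient jitter with known ground truth, and the reference
cohort composition (200 cases: 15 atrophy / 24 inflammation / 20 ectopy /
48 normal / 37 LSIL / 56 HSIL) — so every stage is testable end to end.

## Worked example

The published study's best classifier (1-NN on discrete PLA symbols) is
reported as printed confusion matrices; the evaluation suite recomputes every
derivable metric from the packaged copies:

```sh
$ python examples/06_reference_metrics.py
binary 1-NN / discrete PLA (positive = LSIL or HSIL):
  sensitivity 60%  (95% CI 50-70)
  specificity 79%  (95% CI 70-85)
  accuracy    70%
  MCC 0.395   weighted FP rate 0.313   weighted F-measure 0.697
...
  normal           0.917   0.507  0.364  0.521   0.358
  HSIL             0.714   0.264  0.513  0.597   0.415
  weighted avg     0.420   0.197  0.231  0.292   0.196
  overall accuracy 42%
```

Binary screening finds 60% of lesions at 79% specificity; in the six-class
setting only the two largest classes (normal, HSIL) are ever predicted — the
class-imbalance collapse visible in the per-class rows above.

The other scripts in `examples/` walk through each capability (simulation,
registration, representations, the classifier grid, scheme search), each
printing what it computes and what the numbers mean. The full pipeline is
also available from the shell:

```sh
acetowhite run-all --out runs/demo --seed 7
acetowhite reference-metrics
```

## Layout

- `src/acetowhite/` — library: `synthetic`, `imaging`, `representations`,
  `scheme_search`, `classifiers`, `evaluation`, `reference`, `pipeline`,
  `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, and known limitations.
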