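# migasel

Genetic-algorithm feature selection for left/right hand motor-imagery EEG
classification.

## What it is for

Motor-imagery brain-computer interfaces classify short multichannel EEG
trials (here C3, Cz, C4 at 128 Hz, 9 s per trial) as *left* or *right*
hand imagery, exploiting event-related desynchronization (ERD): during
imagery, the mu (8-12.5 Hz) and beta (13-30 Hz) rhythms lose power over
the sensorimotor cortex contralateral to the imagined hand.  A rich
sliding-window feature set is informative but huge - with the default
windowing a single trial yields **514 windows x 24 features = 12,336
columns** - and most columns mislead the classifier.  `migasel` implements
a wrapper selector: a genetic algorithm searches binary feature masks,
scoring each mask by the test accuracy of a neural network trained on the
selected columns, so feature selection is optimized jointly with the
classifier.

## Pipeline

1. **trial_io** - plain-text trial archives (`manifest.json` + one CSV per
   trial); optional read-only MATLAB-container adapter.
2. **preprocessing** - zero-phase 0.5-30 Hz elliptic bandpass
   (forward-backward filtering).
3. **features** - per 3-s window (384 samples, stride 1, first window at
   sample 255): AR(6) coefficients (Burg) on C3 and C4, plus mean
   amplitude, standard deviation and average power of the Daubechies-5
   level-2 (16-32 Hz) and level-3 (8-16 Hz) detail coefficients.  An
   index map decodes every column to (window, family, channel, level,
   statistic).
4. **ann** - single-hidden-layer tanh network, softmax/cross-entropy,
   z-scoring on training statistics, validation-driven early stopping;
   confusion-matrix metrics (sensitivity, specificity, per-class
   precision, accuracy, with *left* as the positive class) under a
   stratified holdout split or a K-fold rotation (train on K-2 folds,
   validate on 1, test on 1).
5. **ga** - chromosomes are 0/1 masks of length L; roulette-wheel
   selection with P(i) = f(x_i)/sum f, single-point crossover, per-gene
   mutation, elitism, optional feature-count cap (over-cap masks get
   fitness 0), fitness = holdout or K-fold-mean test accuracy.
6. **simulate** - synthetic sessions with lateralized mu/beta ERD plus a
   1/f background, so the whole pipeline is testable without recordings;
   also a planted-signal benchmark matrix for selector recovery studies.
7. **reporting** - selection histograms by family/channel/level,
   selected-features-per-window profiles, GA convergence tables.

## Worked example

```sh
migasel simulate  --out raw --n-trials 140 --seed 5
migasel preprocess --in raw --out filt
migasel extract   --in filt --out feat --stride 8
migasel train     --features feat --out trained --seed 5
migasel select    --features feat --out sel --population 10 --iterations 5 --seed 5
migasel report    --mask sel/best_mask.txt --index-map feat/index_map.csv \
                  --history sel/history.csv --out rep
```

On this synthetic session the run prints, among other lines:

```
extracted 140 x 1560 feature matrix -> feat
testing accuracy 0.810; metrics -> trained/metrics.csv
gen   5  mean 0.846  max 0.893  best popcount 794
best fitness 0.893 with 794 features -> sel
794 selected features summarized -> rep
```

Reading: with stride 8 the extractor emits 65 windows x 24 = 1,560
columns per trial; the network trained on all 1,560 columns classifies
81% of held-out trials correctly, while the GA finds a mask of 794
columns (a 49% reduction) whose holdout test accuracy is 89.3% - the
selector improves accuracy while halving the feature vector.  `rep/`
contains the family/channel histogram and the per-window profile of the
selected features.

Every stage writes a `run_manifest.json` (config echo, seed, version);
rerunning any stage with the same seed reproduces its artifacts
byte-for-byte.

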