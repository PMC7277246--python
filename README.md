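# viscomp

Perceived visual complexity of images from 2AFC paired comparisons.

How visually complex is a real-world scene?  Perceived complexity is a
promising proxy for the perceptual load an image places on an observer, but
it is hard to measure directly: Likert ratings suffer from response bias
and criterion drift.  A cleaner protocol shows observers *pairs* of images
and asks only "which one is more complex?" (two-alternative forced choice).
`viscomp` implements the full analysis pipeline for such an experiment, for
vision scientists and anyone who needs per-image complexity scores:

- **comparison designs** — balanced random pairing so every image takes
  part in approximately the same number of comparisons and every observer
  judges a similar number of trials;
- **rating engine** — TrueSkill-style Bayesian skill rating.  Each image
  carries a Gaussian belief N(μ, σ²) over its latent complexity; every
  comparison is a game won by the chosen image.  With
  c² = 2β² + σ_w² + σ_l² and t = (μ_w − μ_l)/c, the winner/loser update is

      μ_w ← μ_w + (σ_w²/c)·v(t)        μ_l ← μ_l − (σ_l²/c)·v(t)
      σ² ← σ²·(1 − (σ²/c²)·w(t))        (each side)

  where v(t) = φ(t)/Φ(t) and w(t) = v(t)(v(t)+t).  These are the exact
  posterior moments of the winner's skill given the win, so the update is
  the moment-matched Bayes step.  μ is the reported complexity score; the
  fraction of comparisons whose chosen image ends with the higher μ is the
  internal-consistency statistic of the one-dimensional representation;
- **synthetic world** — latent scores ~ Normal(25.0, 5.5), Thurstone
  Case V observers (P(choose A) = Φ((s_A − s_B)/(√2·noise_sd)), plus a
  lapse mixture) and procedural tagged images whose complexity drivers
  (shape count, palette size, texture noise) are known, so every stage is
  testable without any human data;
- **feature battery** — 31 computed scalar statistics (GLCM texture,
  CIELAB colour statistics, channel entropies and variances,
  feature-congestion clutter, edge density, JPEG compression ratio,
  frequency factor, keypoint/region counts), plus externally supplied
  columns for features that need trained models (deep salience, detector
  object counts, search RTs);
- **prediction models** — standardise-then-regress estimators (OLS,
  lasso/ridge with α chosen on a 10-point log grid from 1e-15 to 20, SVR,
  a {128, 64, 32, 1} ReLU MLP, and raw-pixel ridge regression) under
  leave-one-out, 10-fold, or image-grouped cross-validation, scored by
  Pearson's r on pooled validation predictions;
- **part-whole analysis** — decomposition into overlapping discs of
  radius 50 px, disc-level rating, bicubic complexity maps interpolated
  from disc ratings, and mean/sum disc predictors of whole-image scores
  with image-grouped validation splits;
- **object tags** — VOC-style bounding-box annotations turned into
  complexity predictors: per-class mean ratings split by central (largest
  bounding box) vs background occurrence, and presence/count vectors for
  regression.

Estimator classes (`TrueSkillRater`, `ImageFeatureExtractor`,
`ComplexityRegressor`) follow scikit-learn conventions and compose with
its model selection tools; module-level functions expose the same
operations.

## Worked example

Simulate a small 2AFC experiment (100 images, 2000 comparisons, 5
observers with perceptual noise sd 2 in score units) and rate it:

```sh
$ viscomp simulate --items 100 --comparisons 2000 --observers 5 \
    --noise 2.0 --seed 7 --out comparisons.csv --latents-out latents.csv
wrote 2000 simulated comparisons to comparisons.csv
$ viscomp rate --comparisons comparisons.csv --out ratings.csv
rated 100 items; consistency 0.892; wrote ratings.csv
$ head -3 ratings.csv
item_id,mu,sigma
item0039,26.26409605978578,0.9054080336018312
item0024,27.363330723445255,0.8821640596949051
```

Each rated image gets a score mean `mu` (its complexity rating) and an
uncertainty `sigma`.  Here the 2000 simulated judgements agree with the
final ratings on 89.2% of trials — high but imperfect, as expected for a
noisy observer — and the ratings recover the simulated ground truth
closely (Pearson r = 0.986 against the latent scores, mean μ 24.96: the
balanced design keeps the score distribution centred on the prior mean
of 25).

The same run in Python:

```python
from viscomp import DesignSpec, ObserverModel, TrueSkillRater
from viscomp import sample_latent, simulate_comparisons

world = sample_latent(100, seed=7)                    # Normal(25.0, 5.5)
records = simulate_comparisons(
    world, DesignSpec(n_items=100, n_comparisons=2000, n_observers=5,
                      item_ids=world.items(), seed=8),
    ObserverModel(noise_sd=2.0), seed=9)
rater = TrueSkillRater().fit(records)
rater.ratings_["item0039"]   # -> complexity score (mu) for one image
rater.score(records)         # -> consistency statistic
```

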