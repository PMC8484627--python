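# sceneaffect

Contour-feature statistics of line-drawn scenes and their link to valence
and threat judgements.

People judge the emotional tone of a visual environment within a glance,
and mid-level contour statistics — how long, how angular, and how oriented
the lines in a scene are — carry part of that signal: scenes dominated by
long, smooth, horizontal contours (an open landscape with a horizon) tend
to be judged positive and safe, while scenes of short, sharply angular
contours (dense clutter, thorns, jagged rocks) read as negative and
threatening. `sceneaffect` implements the full analysis pipeline behind
that finding for researchers in visual psychophysics and affective scene
perception:

1. **Feature extraction** — line drawings are sets of open polylines
   ("contours") on a pixel canvas. Each drawing is summarised by three
   8-bin, pixel-weighted histograms:
   - *orientation* of each segment (counter-clockwise from horizontal, bin
     centers 0°, 22.5°, …, 157.5°),
   - *length* of each contour, log-binned (centers 1.66 … 1698.24 px),
   - *angularity* at each vertex — turn angle per pixel, log-binned
     (centers 1.38 … 131.83 deg/px).

   Dropping the rarely-populated top length bin and square-root
   transforming gives a 23-feature vector per image.
2. **Valence regression** — OLS of mean 1–9 valence ratings on the 23
   features, with by-name reporting of collinear columns,
   partial-regression (added-variable) series, and separate close/far
   subset fits.
3. **Stimulus generation** — contours are classified into a 2×3×4
   factorial of feature bins (Length × Angularity × Orientation) and
   assembled into 200×150 abstract scene images: contours sampled from one
   bin, scaled down ×4, shifted/shortened to fit, appended until each
   image exceeds 1000 px of contour; 20 images per bin, 480 in all,
   written as SVG plus a manifest.
4. **Choice analysis** — 4-alternative forced-choice trials (pick the most
   positive and most negative of 4 images) are expanded into binary
   observations (chosen-high = 1, chosen-low = 0, neutrals dropped) and
   fit with a random-intercept logistic model,
   `logit P(y=1) = x'β + b_participant`, `b ~ N(0, σ²)`, full factorial
   fixed effects under sum-to-zero coding, Laplace likelihood, and
   Type-III-style likelihood-ratio tests per effect.
5. **Synthetic data** — seed-deterministic generators for controlled
   contours, rating datasets from a known linear model, and simulated
   forced-choice observers, so every stage is testable without the
   access-restricted source images or human data.

The fit/transform stages are scikit-learn style estimators
(`ContourFeatureExtractor`, `ValenceRegression`, `RandomInterceptLogit`)
and compose with sklearn pipelines; module-level functions wrap them for
script use. See `docs/methods.md` for the models, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from sceneaffect import (
    ObserverSpec, build_choice_observations, build_contour_pool,
    fit_logistic_glmm, generate_stimulus_set, likelihood_ratio_tests,
    stimulus_manifest, synth_choice_session, synth_pool,
)

drawings = synth_pool(150, seed=1)              # 3600 contours, 24 bins
pool = build_contour_pool(drawings)             # classify into the factorial
images = generate_stimulus_set(pool, seed=2)    # 480 images, 20 per bin
man = stimulus_manifest(images, 2)
print(len(images), round(man["total_length"].min(), 1))

trials = synth_choice_session(man, ObserverSpec(), n_participants=157, seed=3)
obs = build_choice_observations(trials, man)    # 2 rows per trial
fit = fit_logistic_glmm(obs)
lrt = likelihood_ratio_tests(
    obs, effects=("Orientation", "Angularity", "Length"), full_fit=fit
)
print(lrt[["effect", "chisq", "df", "p"]].to_string(index=False))
est = dict(zip(fit.fixed_names, fit.fixed_effects))
print({k: round(float(v), 2) for k, v in est.items()
       if ":" not in k and k != "(Intercept)"})
```

prints

```
480 1000.1
     effect       chisq  df   p
Orientation 2662.132598   3 0.0
 Angularity 3681.079510   2 0.0
     Length 3598.292275   1 0.0
{'Orientation[both]': -0.36, 'Orientation[diagonal]': -0.36, 'Orientation[horizontal]': 1.13, 'Angularity[high]': -0.9, 'Angularity[low]': 0.9, 'Length[long]': 0.72}
```

Every image exceeds the 1000-px contour budget; with simulated observers
who prefer long, smooth, horizontal contours, all three main effects are
overwhelmingly significant and the fixed effects point the same way:
horizontal orientation, low angularity and long contours push choices
toward "most positive".

A command-line interface mirrors the pipeline
(`sceneaffect extract | fit-valence | genstim | simulate | fit-choice`);
each run writes a JSON run record with its config hash and seed.

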