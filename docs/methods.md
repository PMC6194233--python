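# Methods

## The model and its assumptions

The package models *detection* probability, not establishment: surveys
for emerald ash borer routinely miss young infestations, so the
calibration data (binary survey outcomes) are statements about what a
survey would find, and the model is kept on the same scale to make the
comparison meaningful.

Assumptions, in decreasing order of consequence:

1. **Distance is the only covariate.** Annual city-to-city transfer
   probability is `f(d_ij)` with one global parameter; freight volume,
   passenger traffic, population, climate and host-plant density are all
   ignored.  This is a deliberate bias–variance trade: each extra factor
   would need its own poorly-known coefficient.
2. **Independence of introductions.** Every ordered pair (i, j) and every
   year gets an independent transfer opportunity.  The complement product
   `P_j(t+1) = 1 − Π_i (1 − P_i(t) f(d_ij))` is exact under that
   assumption for event chains that do not share edges; for longer
   horizons it is an approximation that slightly overstates probability
   where multiple paths reuse the same intermediate city.  The test suite
   verifies exact agreement with brute-force event enumeration on small
   networks and short horizons, where no sharing occurs.
3. **Absorbing establishment.** The product includes the `i = j` term;
   with `f(0) = 1` it contributes `(1 − P_j(t))`, so probabilities never
   decrease.  An infested city is never assumed to clear itself.
4. **No local spread.** Flight-scale (km/year) diffusion is far below the
   spatial resolution of a city network and is excluded.

Year semantics: `P(start)` is the seed indicator; applying the recurrence
k times gives `P(start + k)`.  With the default timeline (start 2003) the
calibration year 2015 is 12 steps and the verification year 2017 is 14.

Detections enter twice, differently: calibration compares *calculated*
probabilities with labels (no overwriting — otherwise the objective would
be partially self-fulfilling), while forecasting first overwrites
confirmed detections with 1 (`condition_on_detections`) and then runs the
same recursion forward.  Overwriting detections during the calibration
recursion itself is deliberately not done: the default is the pure model
recursion, which keeps the fitted parameter interpretable as a property
of the dispersal process rather than of the survey schedule.

## Kernels and parameters

| family      | form                | parameter | units | half-distance      |
|-------------|---------------------|-----------|-------|--------------------|
| exponential | `exp(-α d)`         | α         | 1/km  | ln2 / α            |
| normal      | `exp(-β d²)`        | β         | 1/km² | sqrt(ln2 / β)      |
| cauchy      | `1 / (1 + (d/γ)²)`  | γ         | km    | γ                  |

All are used directly as transfer probabilities (`f(0) = 1`), not as
spatial densities — no normalization over space.  The Cauchy family is
fat-tailed: for any α there is a distance beyond which it dominates the
exponential, which is what lets it place non-negligible probability on
confirmed detections hundreds of km from the epicenter while the
thin-tailed families effectively cannot.  Reference calibrated values for
the European EAB system are α = 0.0459 km⁻¹, β = 0.000747 km⁻²,
γ = 10.125 km.

Distances use the spherical law of cosines multiplied by the mean Earth
radius R = 6371.0088 km (the bare formula yields a central angle; fitted
parameters only make sense with d in km).  The arccos argument is clamped
to [−1, 1]; agreement with the numerically stabler haversine form is
better than 0.1 km over random pairs.  No ellipsoidal geodesics: a ~0.3%
spherical error is far below the model's structural uncertainty.

## Calibration

Labels at the reference year: 1 if any detection at or before it, 0 if at
least one negative survey and no detection; unlabelled cities are
excluded, and a detection overrides negatives from any year (the pest
does not disappear; a later negative survey is a miss).  The parameter
minimizes the sum of squared differences between `P_j(reference)` and the
labels.  The objective is smooth and one-dimensional, so the optimizer is
a 200-point log-spaced grid over [1e−6, 1e3] followed by bounded scalar
minimization (scipy, Brent-style) on the bracketing grid interval with
`xatol = 1e−6 · θ_grid` — chosen for reproducibility over cleverness.  A
minimum on the first or last grid point is flagged (`at_boundary`), which
happens when the label set cannot identify the parameter (e.g. only the
seed is positive: any small-enough θ fits perfectly).  Fits with all-equal
labels are refused outright.

## Synthetic data generator

`generate_city_network` emulates the statistical structure of the real
input — a national urban network concentrated around a capital — with a
cluster process: `n_clusters` (default 8) centers uniform in a ±500 km
box around the epicenter, cities Gaussian-scattered around centers with
`cluster_spread_km` (default 80 km), 173 cities by default, and one city
pinned exactly at the epicenter as the seed.  East/west position assigns
a two-country split so regional summaries have groups.  What it does
*not* emulate: real road/rail topology, population-size heterogeneity,
border effects, or coastlines — so passing tests demonstrate the
machinery is correct under the model's own assumptions, not that the
model is right about any particular landscape.

`simulate_survey_data` produces labels from a model run under a known
kernel, either thresholded at p\* (default 0.5, deterministic) or by
Bernoulli draws (seeded).  The parameter-recovery experiment — 150
cities, 12 years, threshold labels, 20 replicates — recovers the
generating parameter with median relative error well under 15% for all
three families.  The generating truths are γ\* = 12 km for Cauchy and the
reference calibrated values α\* = 0.0459, β\* = 0.000747 for the
thin-tailed families: parameters matched to a 12 km half-distance would
leave those kernels unable to bridge typical inter-city gaps, giving
label sets with a single positive on which no method could identify the
parameter.  (Identifiability requires informative labels, not just data.)

## Numerical choices

- Complement products are accumulated as `Σ log1p(−x)`; any certain
  source (`x = 1`) drives the log to −∞ and the complement to exactly 0,
  so seeds stay at exactly 1 rather than 1 − ε.
- Trajectories are clipped to [0, 1] after each step to absorb rounding.
- Probabilities are stored at full double precision; whole-percent
  rendering (round-half-up) happens only at presentation.  Band
  boundaries belong to the band they open: 15.0% is in "15–40%".
- Duplicate coordinates between distinct cities are allowed (a warning),
  with their distance forced to exactly 0.

## Problem sizes

Default test and acceptance runs use networks of 3–173 cities and
horizons up to 19 years; the recovery experiment is 20 replicates × 3
families at n = 150, and the exhaustive recurrence oracle enumerates all
4096 transfer-event combinations on 3-city, 2-year problems.  The whole
suite and the acceptance script each complete in well under a minute on
one CPU.

## Known limitations

- The independence assumption inflates probabilities mildly on dense
  networks over long horizons; the model is best read as an upper
  envelope of detection probability.
- A single global kernel ignores north–south differences in climate
  suitability; the pest may spread slower near its thermal range edge.
- Least squares on 0/1 labels is not a likelihood; no confidence
  interval on θ is produced (a Bernoulli likelihood would be the natural
  extension).
- The bundled named-city fixture is approximate and illustrative, not a
  survey dataset; quantitative claims in the tests rest on the synthetic
  generator, where ground truth is known.
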