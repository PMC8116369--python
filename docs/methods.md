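# Methods

## Scope

`promisgh` implements the normative-value workflow for the PROMIS Scale
v1.2 – Global Health (PROMIS-GH, "PROMIS-10"): IRT scoring of the GMH and
GPH subscales and their 2-item short forms, subgroup reference tables,
anchor-based interpretability thresholds, and a census-margin
representativeness check. Item-parameter *estimation* is out of scope:
PROMIS scores are by convention computed against a fixed calibration, so
parameters are inputs here, never outputs.

## The measurement model

Each scored item follows the logistic graded response model (GRM), the
standard PROMIS model for ordered polytomous items. An item with
discrimination `a > 0` and thresholds `b_1 < … < b_{K−1}` has cumulative
curves

    P*_k(θ) = 1 / (1 + exp(−a(θ − b_{k−1}))),   P*_1 ≡ 1,  P*_{K+1} ≡ 0

and category probabilities `P(k|θ) = P*_k(θ) − P*_{k+1}(θ)`. The latent
trait θ is reported on the T metric, `T = 50 + 10·θ`: mean 50 and SD 10 in
the instrument's calibration population, higher = better health.

Two scoring routes are provided:

* **Response-pattern EAP** (the default): the posterior mean of θ under a
  standard-normal prior, with the posterior SD as standard error. The
  likelihood multiplies category probabilities over *answered* items only,
  so missing responses are handled without imputation; an all-missing
  pattern returns the prior (T = 50, SE = 10) and is flagged rather than
  dropped — dropping is a pipeline-level policy.
* **Summed-score conversion**: the Lord–Wingersky recursion builds the
  likelihood of each attainable raw sum by convolving per-item category
  curves; each sum is mapped to its EAP. Valid only for complete response
  patterns, mirroring how printed conversion tables are used.

The two routes are different estimators. Their sum-score T is exactly the
probability-weighted average of the pattern-EAP Ts of the patterns sharing
that sum (tested to 1e−9), and on model-generated populations they
correlate above 0.997. They are *not* uniformly close pattern-by-pattern:
a discordant pattern such as (1,5,5,5) is improbable under the model, so
the sum-score mixture sits several T-points away from its pattern EAP —
this holds even for four identical items and is a property of summed-score
scoring, not an implementation artifact.

## Numerical choices

* Quadrature: 161 equally spaced nodes on [−8, 8] with normalized
  standard-normal weights. The wide support matters: on [−4, 4] the
  posterior of an all-extreme pattern loses tail mass and its EAP shifts
  by up to ~0.01 on the latent metric; on [−8, 8] the quadrature EAP
  agrees with 10,001-point trapezoid integration to ~3e−12 over all 625
  complete 4-item patterns.
* Rounding is centralized and half-up (0.5 away from zero): T-scores to 1
  decimal, thresholds to integers, percentages to 1 decimal. Internal
  computation is never rounded. Half-up is forced by the threshold
  procedure itself: a midpoint of 50.5 must become a cut point of 51.
* Vectorized population scoring accumulates log-likelihoods per item
  (`log 0 = −inf` is deliberate: impossible categories zero the
  posterior node) and normalizes with a max-shift for stability.

## Item parameters

The proprietary US calibration parameters are not redistributable, so the
package ships a clearly labelled **synthetic** default set
(`data/item_parameters_synthetic.csv`): slopes 2.5–3.4 logit units —
global-health items calibrate as highly discriminating — with thresholds
spread over the latent range, Global06 (everyday physical activities)
shifted easy, and Global10 given the lowest slope of its scale. Users with
access to an official calibration supply it as a CSV of the same layout;
nothing else changes. T-scores produced under the synthetic set are
internally consistent but are not comparable to officially scored data.

## The anchor-based thresholds

Respondents are grouped by the 5-category general self-rated health anchor
(Global01); per-group mean T-scores are computed in fixed label order
(poor → excellent); each cut point is the half-up-rounded midpoint of two
adjacent means. Non-monotone adjacent means yield a warning but no
isotonic correction — no adjustment rule is defined for the procedure.
Classification of a non-integer T-score rounds it to an integer first,
because the bands tile the integer T axis.

## The representativeness check

Sample category percentages for age band (18–39 / 40–65 / >65, a coarser
scheme than the reference-table bands), gender, education, region and
ethnicity are compared to census percentages; the deviation is the
absolute difference in percentage points and the sample passes when the
maximum deviation is strictly below the criterion (default 2.5). Boundary
conventions are declared, not inferred: 18–39 and 40–65 include their
endpoints, >65 excludes 65. "Unknown" buckets are reported but excluded
from deviations. Printed census margins may sum to 99–101 because of
rounding and are accepted as such.

## The synthetic-population generator

The generator emulates a general-population web panel: gender × age-band
strata with configurable proportions; a bivariate-normal latent pair
(θ_GMH, θ_GPH) with stratum-specific means, unit SDs and correlation
ρ = 0.6 by default (a placeholder — the true inter-trait correlation in
such panels is not published, and the test suite is written to be
insensitive to it); GRM-sampled responses per item, written as *raw*
administration codes (reverse-direction items unreversed, the pain item as
0–10) so generated data exercises the full recoding path. The two
standalone items load on the standardized composite `w·θ_GMH +
(1−w)·θ_GPH` with w = 0.5, which couples the anchor item to overall
health. Missingness is completely at random, default rate 0 (the emulated
survey did not allow skipping); non-zero rates exist to exercise the
missing-data path. All draws come from one seeded generator in a fixed
order (strata → demographics → latents → items → masks), so a seed fully
determines the population.

Default stratum means are built additively from published subgroup T
levels mapped to the latent metric ((T − 50)/10), anchored at totals of
−0.53 (mental) and −0.48 (physical). Because EAP estimates shrink toward
the prior mean, a population generated at latent mean −0.53 scores an
observed mean T about 0.6–0.8 points closer to 50 than the nominal target;
recovery tests therefore use a 1.5-point tolerance and the shrinkage is
expected, not a defect. Within-band ages are uniform except the 35–44 and
65–74 bands, which are skewed young so a single population satisfies both
banding schemes' margins (and mirrors declining panel coverage with age).

What the generator does **not** emulate: panel-recruitment bias,
item-level response styles, differential item functioning between
languages, and exact matching of any published item-response marginal.
Passing tests therefore demonstrate that the machinery is correct under
the stated model, not that the model captures every feature of real panel
data.

## Problem sizes

Property tests enumerate all 5⁴ = 625 complete patterns of a 4-item
subscale exactly; oracle comparisons use 10,001-point trapezoid
integration; population-level tests use n = 2,000–5,000 synthetic
respondents and Monte-Carlo checks up to 50,000 draws, sizes at which
sampling error is comfortably inside the stated tolerances.

## Known limitations

* Shipped parameters are synthetic; scores are not officially comparable.
* The CI for the difference from a reference mean is one-sample normal
  with the reference treated as a known constant; published CIs for such
  comparisons may use other conventions, so CIs are reported but not
  treated as reproduction targets.
* The threshold procedure inherits the reliability of a single anchor
  item; thresholds from small anchor groups are noisy, and empty anchor
  categories abort the derivation by design.
* Age is taken at survey time; no weighting or post-stratification is
  applied anywhere (reference samples are constructed to be
  representative).
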