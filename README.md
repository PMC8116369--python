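# promisgh

IRT scoring and population reference values for the **PROMIS Scale v1.2 –
Global Health** (PROMIS-GH, also called PROMIS-10).

Patient-reported global health is usually summarized as two subscale
scores — Global Mental Health (GMH: items Global02/04/05/10) and Global
Physical Health (GPH: items Global03/06/07/08), each with a 2-item short
form — expressed as T-scores (mean 50, SD 10 in the instrument's
calibration population; higher = better health). Interpreting an
individual's or a patient group's T-score requires *reference values*
from a general population, and cut points that translate scores into
plain labels (poor / fair / good / very good / excellent). This package
implements that entire workflow for epidemiologists and outcomes
researchers:

* **Instrument logic** — the 10 items, recoding of the 0–10 pain item to
  5 categories, reverse coding of the fatigue and emotional-problems
  items, subscale membership (`promisgh.instrument`).
* **GRM scoring engine** — graded-response-model category probabilities
  `P(k|θ) = 1/(1+e^{−a(θ−b_{k−1})}) − 1/(1+e^{−a(θ−b_k)})`,
  response-pattern EAP scoring by quadrature (handles missing items), and
  Lord–Wingersky summed-score → T conversion tables (`promisgh.grm`).
* **Reference tables** — item distributions, per-subgroup (total, gender,
  six age bands) n / mean T / SD, differences from a fixed reference
  mean, long-vs-short-form gaps (`promisgh.popref`).
* **Interpretability thresholds** — the three-step anchor procedure:
  group by the general self-rated health item, average T per group, cut
  at half-up-rounded midpoints of adjacent means (`promisgh.thresholds`).
* **Representativeness** — sample-vs-census margin deviations with a
  strict 2.5-percentage-point criterion (`promisgh.representativeness`).
* **Synthetic populations** — a seeded generator producing panel-like
  respondent data with known latent traits, so every stage is testable
  end to end (`promisgh.synthetic`).

The published Dutch general-population tables (item distributions,
reference values, thresholds, census margins) ship as plain-text data and
are reproduced by the test suite; the US reference values and US
thresholds are stored verbatim as comparison constants, never computed.

The shipped default item parameters are **synthetic** (realistic slopes
and thresholds, clearly labelled): the official US calibration is not
redistributable. Supply your own parameter CSV (`item_id,a,b1..b4`) to
score on an official metric.

## Worked example

```sh
promis-gh simulate --n 4370 --seed 1 --out panel.csv
promis-gh reference-table panel.csv --out ref.csv
promis-gh thresholds panel.csv
promis-gh check-rep panel.csv
```

prints (abridged):

```
             n         GMH      GMH-2a         GPH      GPH-2a
subgroup
total     4370  45.4 (9.3)  46.0 (8.8)  45.7 (9.4)  46.1 (9.0)
male      2081  46.0 (9.3)  46.6 (8.8)  46.2 (9.4)  46.4 (9.0)
female    2289  44.9 (9.2)  45.4 (8.7)  45.3 (9.4)  45.7 (9.0)
18-34      901  46.1 (9.1)  46.6 (8.5)  48.3 (9.5)  48.4 (9.0)
...
GPH thresholds: (36, 44, 52, 59)
  poor       < 36
  fair       36-43
  good       44-51
  very good  52-58
  excellent  >= 59
max deviation 2.20 (ethnicity:western_immigrant) vs criterion 2.5: PASS
```

Reading this: the simulated panel of 4,370 adults has a mean GMH T-score
of 45.4 and GPH of 45.7 — about half a standard deviation below the
calibration mean of 50, the level the generator is configured to emulate
(EAP estimates shrink slightly toward 50, so observed means sit a little
above the latent targets of 44.7/45.2). A GPH score of 47 would fall in
the "good" band (44–51), and the sample's demographic margins deviate
from the census by at most 2.2 points, within the 2.5-point criterion.
The same objects are available programmatically:

```python
from promisgh import eap_pattern_score, load_default_instrument, load_default_parameters

spec = load_default_instrument()
params = load_default_parameters()
items = [params[i] for i in spec.subscale_items("GPH")]
result = eap_pattern_score([2, 5, 3, None], items)  # fatigue item skipped
print(f"T = {result.t_score_reported}, SE = {result.se_t:.1f}")
# T = 48.0, SE = 4.5
```

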