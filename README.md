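# vitalcentiles

Age-conditional centile curves (1st–99th percentile) for heart rate and
intra-arterial blood pressure, derived from continuous bedside-monitor
streams sampled every 5 seconds.

Normal ranges for vital signs in children change rapidly with age: the
median heart rate of a newborn is nearly twice that of an adolescent.
Existing reference ranges are mostly consensus-based and coarse.
`vitalcentiles` builds empirical, age-resolved percentile curves directly
from high-frequency monitor data, using the volume of routine observations
(thousands of samples per patient per day) to resolve the full shape of each
distribution rather than just a mean and spread.

## Method in brief

1. **Age partition.** Patients contribute observations to 43 age groups:
   30 day-level groups (Day 1 … Day 30, for the rapid neonatal transition)
   and 13 coarse groups from 0–3 months up to 15–18 years. A month is
   365.25/12 days, a year 365.25 days; intervals are half-open with the
   upper bound included.
2. **Quality filters.** Values outside the open interval (0, 300) are
   discarded as artefact; episodes of cardiac pacing are detected by a
   small neural-network classifier on two-minute windows, with its decision
   threshold calibrated so that at least 98 % of non-paced windows are
   retained; each patient must contribute at least 10 000 samples
   (≈ 14 hours of monitoring) to an age group to be counted in it.
3. **Equal patient weighting.** Each patient's observations in a group are
   reduced to a normalized histogram over the integer support 1–299, and the
   group distribution is the arithmetic mean of the per-patient histograms.
   A patient monitored for a week therefore counts no more than one
   monitored for a day.
4. **Centiles.** All 99 percentiles are read from each group's distribution,
   smoothed across age with locally weighted regression (LOWESS), and
   re-monotonized within each age group. Parametric summaries (gaussian,
   logistic, and LMS/Box-Cox-normal fits) and linear quantile regression are
   available for compact reporting, with a sup-norm discrepancy statistic to
   flag groups — typically mean arterial pressure — whose heavy-tailed,
   skewed distributions a gaussian cannot represent.
5. **Reference comparison.** Derived curves can be compared against
   published reference-range tables: mass outside the published cutoffs and
   signed percentile differences per age band.

Because real monitor streams cannot be redistributed, the package includes
a synthetic cohort generator with known ground truth (age-interpolated
gaussian and sinh–arcsinh families, pacing and artefact injection, terminal
digit preference) used throughout the test suite to verify that the pipeline
recovers the distributions it is fed. See
[docs/methods.md](docs/methods.md) for the full methods note.

## Worked example

Simulate a small cohort, filter it, build group distributions and read off
centiles:

```python
import numpy as np
from vitalcentiles.synthetic import CohortConfig, simulate_cohort
from vitalcentiles.quality import plausibility_filter
from vitalcentiles.pipeline import build_group_distributions
from vitalcentiles.centiles import build_centile_table

config = CohortConfig(
    n_patients=12,
    seed=7,
    variables=("HR",),
    stay_sampler=lambda rng, n: np.full(n, 20.0),          # 20-hour stays
    age_sampler=lambda rng, n: rng.uniform(40, 3000, n),   # ages in days
)
metadata, stream = simulate_cohort(config)

observations, n_discarded = plausibility_filter(stream.observations)
distributions, report = build_group_distributions(
    observations, metadata, min_records=10_000
)
coarse = [d for d in distributions if not d.age_group.startswith("Day")]
table = build_centile_table(coarse)
print(table.data[["p5", "p50", "p95"]].round(1))
```

Output:

```text
                 p5    p50    p95
0-3 months    119.2  148.1  177.5
18-24 months   92.4  120.6  148.6
2-3 years      89.9  117.7  145.5
3-4 years      85.2  112.2  139.9
4-6 years      80.8  107.5  134.3
6-8 years      76.4  102.6  128.7
```

Heart-rate centiles fall with age, as expected from the generator's truth,
and each row carries the full set of columns `p1` … `p99`.

## Command-line interface

The same pipeline is available as a CLI. With a YAML configuration

```yaml
outdir: out
seed: 7
min_records: 10000
simulate:
  n_patients: 12
  variables: [HR, MBP]
  implausible_rate: 0.002
  paced_fraction: 0.05
```

running

```bash
vitalcentiles run --config pipeline.yaml
```

prints

```text
pipeline complete: 20 group distributions, 8 centile tables -> out
```

and writes per-variable centile CSVs (raw and smoothed, day-level and
coarse), the filter report, group moments, exclusion counts and a JSON
manifest into `out/`. Individual stages are also exposed:
`vitalcentiles simulate`, `filter`, `build`, `compare` (against a
reference-range CSV) and `agegroups` (the canonical 43-group table).

## Reproduction

All results are reproducible from a fixed seed:

```bash
pip install --no-build-isolation -e ".[test]"
pytest                                   # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the headline computations — age-partition
counts, equal-weighting invariance, moment closed forms, LMS parameter
recovery, pacing-filter calibration rates, gaussian-fit discrepancies on
mesokurtic versus leptokurtic groups, the quantile-regression optimality
gap, and percentile recovery on a 200-patient × 20 000-observation cohort —
and writes each quantity with the sample size it was computed from.

## Package layout

| Module | Contents |
| --- | --- |
| `vitalcentiles.ages` | 43-group age partition and assignment |
| `vitalcentiles.quality` | plausibility, pacing and minimum-record filters |
| `vitalcentiles.distributions` | per-patient histograms, equal-weight aggregation, moments |
| `vitalcentiles.centiles` | percentile extraction, smoothing, parametric fits, quantile regression |
| `vitalcentiles.reference` | comparison against published reference ranges |
| `vitalcentiles.synthetic` | ground-truth cohort generator with artefact injection |
| `vitalcentiles.io` / `pipeline` / `cli` | CSV formats, pipeline driver, command line |

## Limitations

The synthetic generator is a statistical stand-in for real monitor data: it
models stationary per-patient distributions, idealized pacing episodes and
simple artefact patterns, not physiology. Centiles describe the distribution
of observed values in monitored patients and are not by themselves treatment
thresholds.
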