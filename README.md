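# nephrokit

Estimating a patient's **total nephron number** from routine clinical data
— and the study machinery around that estimate.

The number of nephrons (filtering units, approximated by glomeruli) varies
close to eight-fold between individuals and is thought to drive the
progression of chronic kidney disease: fewer nephrons force each remaining
glomerulus to hyperfilter. Counting nephrons in a living patient is
impossible directly, but a needle-biopsy section plus the renal cortex
volume contain enough information for a stereological estimate. This
package implements that estimator and the surrounding toolkit for a
prospective CKD biopsy cohort: cortex volumetry from tomographic slices,
clinical endpoint construction, the log-rank sample-size design, and
synthetic-data generators that verify every estimator against known truth.

## The estimator

Glomeruli are modelled as spheres of common in-vivo radius *r* distributed
homogeneously in the cortex. Profiles with observed diameter under 5 µm
(cut-off radius *r₀*) cannot be counted, so the mean countable-profile
area is

&nbsp;&nbsp;&nbsp;&nbsp;*A_h = π (2/3 r² + 1/3 r₀²)*

With *N_s* countable profiles on a measured cortex area
*A_cortex = L·d_b* (cortex length × needle internal diameter, corrected
for the 31%/43% volume shrinkage of embedded tissue and glomeruli via the
cube-root factors 0.883/0.829), the glomerular volume fraction of the
cortex equals the profile-area fraction (Delesse principle):

&nbsp;&nbsp;&nbsp;&nbsp;*VF = N_s · A_h / A_cortex*

and the total count follows from the cortex volume *V_cortex* and the
single-glomerulus volume:

&nbsp;&nbsp;&nbsp;&nbsp;*N_total = VF · V_cortex / ((4/3) π r³)*

*V_cortex* comes from tomographic slice summation (Σ area × spacing) or,
in routine practice, from a fitted linear estimating equation over
clinically available features. See `docs/methods.md` for assumptions,
corrections and design choices.

## Worked example

A biopsy with two usable sections (13 glomeruli, one globally sclerotic,
16G needle), a cortex volume of 95 cm³ and cohort mean radius 100 µm:

```bash
$ nephrokit estimate --sections sections.csv --cortex-volume 95cm3 --r 100 --out report.json
wrote report.json (1 patients)
```

The audit report echoes every intermediate:

| quantity | value | meaning |
|---|---|---|
| `mean_profile_area_um2` | 20950.5 | *A_h* at r=100 µm, r₀=2.5 µm |
| `cortex_area_um2` | 1.8315e7 | (13.6 mm / 0.8837) × 1.19 mm, in µm² |
| `n_profiles_used` | 13 | countable profiles over usable sections |
| `volume_fraction` | 0.01487 | 13 × A_h / A_cortex |
| `total_number` | 337264 | VF × 95 cm³ / single-glomerulus volume |
| `total_number_nonsclerotic` | 311320 | same, excluding 1 sclerotic profile |
| `adequacy` | adequate | ≥ 8 glomeruli in total |

So this kidney is estimated to hold ≈ 3.4 × 10⁵ nephrons — low-normal, as
expected for a CKD biopsy cohort (reported population extremes span
roughly 2.3 × 10⁵ to 1.8 × 10⁶ per kidney).

The study design at its stated parameters (two-tailed log-rank, α = 0.05,
power 0.80, event rates 0.1 vs 0.2, LBW prevalence 0.095, 2-year accrual,
3 further years of follow-up):

```bash
$ nephrokit design sample-size --out design.json
n_lbw=50 n_normal=476 recruit=585 (protocol)
$ nephrokit design power --n-lbw 50 --n-normal 476 --reps 2000 --seed 1 --out power.json
power=0.883 (mc_se=0.007)
```

50 low-birth-weight and 476 normal-birth-weight patients (526 total;
inflating for 10% withdrawal gives 585, rounded up to 600 in practice).
The Monte-Carlo check shows the events-based formula is conservative at
this unbalanced allocation: simulated power at 50/476 is ≈ 0.88 against
the 0.80 target.

Other subcommands: `cortex-volume`, `fit-cortex-model`,
`predict-cortex-volume`, `endpoints` (analysis-ready time-to-event table),
`simulate cohort|biopsy|phantom`, `validate`. All accept `--config
config.yaml` holding the shrinkage fractions, cut-off, gauge table, stage
bands and design spec.

## Library surface

```python
import nephrokit as nk

geom = nk.GlomerularGeometry(r=100.0, r_o=2.5)
spec = nk.BiopsySpecimen([nk.BiopsySection([4.2, 3.1], 6, 1),
                          nk.BiopsySection([6.3], 7)], needle_gauge=16)
est = nk.estimate_nephrons(spec, nk.Volume(95.0, "cm3"), geom)
est.total_number        # 337263.9
```

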