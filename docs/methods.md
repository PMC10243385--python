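# Methods

This note records the modelling conventions the package implements, the
choices made where the method family leaves room, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

A formulation study is a table of runs: seven inputs in raw units (drug,
polymer and surfactant mass fractions in percent, organic/aqueous volume
ratio, stirring speed in rpm, stirring time in seconds, dilution ratio) and
up to four measured attributes (median particle size in µm, distribution
uniformity, encapsulation efficiency and drug loading in percent). Inputs
are bounded by the declared design domain (drug 0–2 %, polymer 10–20 %,
surfactant 0.5–2 %, O/W 0.1–0.4, speed 1,000–3,000 rpm, time 60–120 s,
dilution 2–10); loading a value outside the domain is an error unless the
strict flag is lowered.

Unassayed responses are *missing*, never zero, at the data layer. The only
place zeros may be substituted is `response_vector(..., "zero_fill")`, which
exists for structurally zero quantities: drug loading of drug-free runs is
genuinely 0 %, so the loading model is fitted on all 24 runs with zero
fill, whereas encapsulation efficiency is undefined without drug and those
8 runs are dropped (n = 16). These two policies are what make the reported
ANOVA degrees of freedom — (4, 19) for loading and (11, 4) for efficiency —
internally consistent.

### Size-distribution summaries

`median_volume_diameter` anchors the cumulative volume curve at each class
center with a half-mass convention (half of a class's volume counts below
its center) and interpolates linearly in cumulative fraction versus
log10(size), the standard laser-diffraction convention; `uniformity` is the
volume-weighted mean absolute deviation of class centers from that median,
divided by the median. It is dimensionless, non-negative and invariant
under rescaling all sizes by a common factor. For the two-class
distribution {10, 30} µm at equal volumes this gives D(v, 0.5) = √300 ≈
17.32 µm and uniformity 1/√3 ≈ 0.577; a linear-size interpolation would
give 20 µm and 0.5 instead. The log convention was fixed before any tests
were written and is the package's documented choice.

## Fuzzy basis and fitting

Membership functions are order-2 B-splines: triangular hats with equally
spaced peaks including both domain endpoints, so memberships sum to one
everywhere and at most two are non-zero. Set densities of 2 and 3 carry the
linguistic labels LOW/HIGH and LOW/MID/HIGH. Peaks are *not* moved by the
fit: with three-level designs the printed model-quality figures of the
reference study are reproduced exactly by equispaced peaks (a numerical
search over adapted peak positions was explored during development and
could not do better for these structures), and fixed peaks keep rule
thresholds at predictable positions (the midpoints between design levels:
polymer 12.5/17.5 %, speed 1,500/2,500 rpm, and so on).

Inputs are used in raw units — no standardisation — because the basis
functions are scale-free (each one is defined on its own input's domain)
and rule thresholds are then quoted in the units practitioners use.

A model is additive over tensor-product submodels and fitted by ridge least
squares with λ = 1e-6. No intercept is added; constants live inside each
submodel's basis. Since k submodels then share k−1 redundant constants,
the *effective* parameter count is `total basis − (k − 1)`; all reported
degrees of freedom, SRM penalties and ANOVA ratios use it. The ridge term
resolves the numerical redundancy but makes coefficients very slightly
non-equivariant under affine response rescaling (at the 1e-8 level for
these data); rules therefore report predicted corner values, never raw
coefficients.

ANOVA convention: `df1 = p` (effective parameters), `df2 = n − 1 − p`,
`f = (SS_model/df1)/(SS_res/df2)`, with the significance band taken from
the F tail probability (`<0.01`, `<0.05`, `<0.1`, `n.s.`). Model
predictability is the training-set determination coefficient in percent;
at n = 24 the package deliberately reports no generalisation estimate —
there is no held-out data in this workflow, and the ANOVA is the only
accuracy check.

## Structure search

The SRM score is `MSE × (1 − √(ρ − ρ ln ρ + ln n / 2n))⁻¹` with ρ = p/n,
infinite once the radicand reaches one (and always for p ≥ n). The search
is greedy: from the empty model, enumerate candidate refinements (add a
univariate submodel at any allowed density; raise a density; extend a
submodel with a new input; merge two submodels; delete; split), fit each,
and accept the lowest-scoring candidate only if it improves the incumbent
score by at least the relative margin `min_improvement` (default 0.25).
Ties break by fewer parameters, then enumeration order, so the search is
deterministic and its full history is recorded.

The margin is the pruning-strength knob. With ~10–15 candidate moves per
iteration at n = 24, a plain "any improvement" rule accepts chance
improvements from noise in roughly half of synthetic replicates; requiring
a 25 % score improvement keeps the false-discovery rate of spurious terms
below a few percent in the single-term benchmark (calibrated on separate
seed bases) while leaving genuine structure — whose improvements at these
signal levels are several-fold — untouched.

Two honest limitations, both visible in the test suite:

* The drug-loading interaction (drug × polymer) is statistically marginal
  against the univariate drug-only model on these data (F ≈ 3.0, p ≈ 0.07
  for the two extra parameters; the univariate model already reaches
  R² = 93.3 %). Under the SRM score the simpler model wins *regardless of
  search path*, so the search reports {drug} where the reference software
  reported the interaction. No selection rule can accept an effect of this
  size while reliably rejecting same-sized noise improvements; the package
  prefers the reliable behaviour and fits the published structure directly
  when reproducing the study.
* The encapsulation-efficiency structure printed in the study (11 effective
  parameters on 16 runs) has an infinite SRM penalty here; it is likewise
  fitted as a fixed structure, reaching R² = 89.76 % against the published
  90.08 % — close but not exact, the residual difference being whatever
  internal convention the original proprietary software used.

## Published model structures

The bundled reproduction fits the four responses with the structures the
reference study printed, with densities reconstructed from its rule
numbering and degrees of freedom:

| response | structure | n | p | R² (%) | f (d.f.) |
|---|---|---|---|---|---|
| size | polymer(3) × speed(3) | 24 | 9 | 92.90 | 20.35 (9, 14) |
| uniformity | drug(2) × speed(3) + PVA(2) + time(3) × O/W(2) + dilution(2) | 24 | 13 | 85.26 | 4.45 (13, 10) |
| EE | polymer(2) × O/W(3) + drug(2) × time(3) | 16 | 11 | 89.76 | 3.19 (11, 4) |
| DL | drug(2) × polymer(2) | 24 | 4 | 94.86 | 87.62 (4, 19) |

(The table restates what `asmod reproduce` computes at run time; nothing in
it is stored.)

## Rules, trees and grids

Rule extraction evaluates the model at every fuzzy-peak corner of one
submodel while the other submodels contribute their mean over the training
rows (not zero — with additive offsets, zeroing them would shift every
corner and could flip LOW/HIGH labels). Corner values are min-max
normalised per submodel into membership degrees; a corner at degree ≥ 0.5
reads HIGH. A submodel whose corners are constant is flagged degenerate and
reported at degree 0.5. Rule numbering is consecutive across submodels in
model order — a package convention; no canonical ordering exists.

Decision trees split each input at the membership-0.5 boundaries. Each leaf
carries the *band* (exact minimum and maximum) of model outputs over its
cell, computed by enumerating cell vertices and interior peaks — exact
because the surface is piecewise multilinear with kinks only at peaks. The
band always contains the model prediction anywhere in the cell, which is
the property the tests verify.

Partial-effect grids sweep one or two inputs over their domain; submodels
not involving a swept input contribute their training mean, and in mixed
submodels the unswept inputs sit at their training-mean value.

## Design generation and formulation selection

Balanced designs assign each factor's levels in equal counts by
construction and then improve space-filling by a seeded exchange heuristic
(swap two runs' levels within one factor; keep the swap if the minimum
pairwise distance in normalised level space grows, with mean distance as
tie-break; 2,000 iterations). Balance is exact and testable; spread is
heuristic and the proprietary generator's exact layout is not reproduced —
only its balance property.

Inverse selection evaluates every fitted model on a full factorial grid of
the input space (default five levels per input, 5⁷ ≈ 78k candidates —
exhaustive and auditable at this dimensionality), keeps candidates meeting
all constraints, and ranks them by one objective. Every returned candidate
re-verifies its constraints by direct prediction.

## Synthetic benchmarks

The generator draws inputs from the same balanced three-level layout the
real study used (or uniformly at random), adds tensor-spline surfaces
defined by corner tables, and Gaussian iid noise. Defaults mirror the study
conditions: 24 runs, seven inputs, three levels. The structure-recovery
benchmark uses a single univariate term with noise at 5 % of the surface
range, i.e. a clearly identifiable effect; passing it shows the search does
not hallucinate structure at study-scale n, *not* that it would resolve
marginal interactions (see the drug-loading limitation above) or survive
correlated noise, model misspecification, or measurement error in the
inputs — none of which the generator emulates.

All randomness flows from explicit seeds (design seed, noise seed derived
from it, replicate seeds spawned from the ground truth's seed), so every
simulation and search is reproducible bit for bit.

## Numerical notes

* Ridge λ = 1e-6 on the raw basis; bases are O(1), so the bias is far below
  printed precision for all reported statistics.
* Memberships are evaluated by linear interpolation between peaks; the
  partition-of-unity identity holds to < 1e-12, which is what lets
  saturated fits reproduce group means to < 1e-3 relative error.
* Out-of-domain inputs are clamped to the domain by default (predictions at
  the boundary value); with clamping disabled they raise.
* The search stops early once the mean squared error falls below 1e-10 of
  the response's mean square: beyond that, score differences are
  ridge-rounding noise, not structure.
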