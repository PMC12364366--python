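# Methods

This note documents the model implemented by `mff`, the choices made
where the design was genuinely open, the calibration of the
macrophage-side constants, and the limitations a user should keep in
mind. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model overview

The simulator is a stochastic cellular automaton on an `n × n` lattice
(default 40 × 40, pixel size Δx = 10 μm, time step τ = 20 min). Each
pixel holds at most one cell. Two mediator concentration fields live
on the same lattice in dimensionless units: PIM (pro-inflammatory, a
TNF-α-like lump) and AIM (anti-inflammatory, TGF-β/IL-10-like).

One tick executes a pinned sub-step order:

1. **Death sweep** — a cell dies when its age reaches its sampled
   lifespan (inclusive boundary); its pixel frees immediately.
2. **Movement** — every live cell, in a freshly randomized order,
   first attempts a chemotactic jump (probability `k·max(0, Δc)`
   toward each up-gradient neighbour on the diffusible PIM field,
   normalized when the sum exceeds 1; the frozen implant field exerts
   no pull), succeeding only onto an empty pixel; failing that, one
   unbiased step to a uniformly drawn neighbour, again only if empty.
3. **Activation updates** from the current local and lattice-mean
   mediator levels (details below).
4. **Phenotype transitions** with lifespan re-sampling whenever the
   lifespan class changes (naive 24 ± 6 h, activated macrophages
   48 ± 12 h, fibroblasts 336 ± 84 h; truncated normal by default,
   exponential with the same mean available as a switch for parity
   with the earlier macrophage-only model).
5. **Secretion** — per-phenotype rates deposited over the secreting
   cell's 3 × 3 footprint (a cell is one pixel wide and secretes
   around its membrane; the spreading is mass-conserving at edges) and
   accumulated into the cumulative-secretion counters.
6. **Field update** — each mediator redistributes by its 3 × 3 kernel
   and decays by `1 − exp(−τ/lifetime)`. The kernel's neighbour
   probability is the 1-D Gaussian displacement form
   `P = (Δx/√(4πDτ))·exp(−Δx²/(4Dτ))`; with the defaults this gives
   0.0210/0.832 (stay) for PIM (D = 900 μm²/min) and 0.0226/0.820 for
   AIM (D = 780 μm²/min). The boundary is reflecting — flux that
   would leave the grid stays at its source — so with zero decay the
   total mass is conserved exactly (an absorbing option exists).
7. **Recruitment** — for each species (M0, F0, F1) a configurable
   number of candidate pixels is drawn from the placement region
   (whole grid, border, or a circular crown; fractional attempt rates
   are Bernoulli-rounded per step) and accepted with a probability
   composed of second-order Hill terms combined as independent chances
   `1 − Π(1 − hᵢ)`. Macrophage recruitment is driven by the *total*
   PIM over the lattice (including the frozen implant PIM, through its
   own term) and the local AIM; fibro recruitment by the *local* PIM,
   AIM and (with an implant) local frozen PIM at the candidate pixel.
8. **Aging and bookkeeping** — ages advance by τ; one trace row per
   step records phenotype counts, field totals, cumulative secretion
   and the cumulative chemotactic move count N_c.

All randomness flows from a single per-run seed through five named
child streams (initialization, movement, lifespans, recruitment,
activation), so a run is a pure function of (config, seed) and traces
are bit-identical across reruns. The movement loop is compiled with
numba and consumes pre-generated uniforms from the movement stream.

## Activation kinetics

Most rates use the Hill form `h(x) = (a·x)² / ((a·x)² + k)`.

Fibro cells follow the published template:

    F1act += F1ActScalar · h(local AIM; k = 0.85)
                         · 1/(1 + SOCS/F1SOCSInfinity)
           − FNegativeFeedbackRate · F1act

with F1ActScalar = 0.065, FNegativeFeedbackRate = 0.003 and
F1SOCSInfinity = 7. A fibrocyte becomes a fibroblast when F1act
exceeds 0.5 (by analogy with the macrophage thresholds); the
differentiation is latched by default, with a reversible mode behind a
flag. Fibro cells accrue SOCS from their own activation with the same
constants as macrophages.

Macrophages mirror the template. The M1 input is the local PIM
(diffusible + frozen) plus a weighted lattice mean; the M2 input is
the local AIM plus its lattice mean, plus — when an implant is present
— the frozen PIM with weight 0.5, since a foreign body triggers
secretion of both mediator classes. Three structural choices matter:

* **SOCS inhibits only the M1 increment.** SOCS is the lumped
  suppressor of the pro-inflammatory JAK/STAT arm; leaving the M2
  drive uninhibited is what produces the observed resolution switch
  from the M1-dominated acute phase to the M2/fibrotic chronic phase.
* **PIM acts locally, AIM systemically.** The lattice-mean weight is
  0.2 for PIM and 1.0 for AIM. A large global PIM weight makes every
  cell on the lattice echo the pro-inflammatory state of a few
  secreters and the response never resolves.
* **Cross-talk.** M1 cells secrete AIM at a small rate (an
  IL-10-like self-limiting brake) in addition to PIM; this is what
  raises AIM secretion under a purely pro-inflammatory stimulus.

Macrophages also receive a small spontaneous activation kick
(probability 0.007 per cell-step, kick of 0.24/0.37 on M1act/M2act).
Without it the deterministic update has a dead fixed point at
PIM = AIM = 0, whereas unstimulated tissue measurably secretes both
mediators; the kick size and rate are calibrated against the
unstimulated-control secretion levels.

## Parameters

Fibro-side and physical constants carry their published defaults
(Table-style registry in `mff.params.ModelParams`): fibro secretion
0.35 PIM / 0.85 AIM per step (0.55/0.60 under pathological stimulus,
secreted by fibrocytes and fibroblasts alike), recruitment scale terms
30 (3 with a biomaterial), recruitment cooperative parameters
a = 0.5/0.2/0.7/1.0, diffusion coefficients 900/780 μm²/min,
chemotaxis constant k = 0.5 (literature-derived alternative 0.02).

The macrophage-side constants were inherited by the model family from
an earlier macrophage-only simulator and are not printed in the
reference tables, so they live in the `MacKinetics` sub-registry as
documented, overridable defaults. They were calibrated — as the model
family prescribes — so that the simulator reproduces the published
secretion magnitudes and implant-vicinity counts under the exact
validation protocols; the calibrated values are the field defaults in
`mff/params.py` (gains 0.065, Hill scales 0.85, activation decay 0.01
per step, SOCS accrual/decay 0.05/0.01, secretion rates 0.05 PIM per
unit M1act, 0.022 AIM per unit M2act, 0.006 AIM per unit M1act,
intermediate cells at half rate, mediator lifetimes 570/600 min).
Mediator "intrinsic lifetime" is exposed as a lifetime in minutes and
applied as a per-step exponential decay fraction.

Recruitment geometry is scenario-specific where the protocols leave it
open. The pathological-validation ensembles place recruits on the
published circular crown hugging the stimulus (inner Chebyshev radius
= stimulus half-width + 1 px, width 2 px). The biomaterial validation
places them on a crown in the outer tissue (two pixel rings just
inside the border, margin 9 + 1, width 1.5) with 2.5 macrophage and
1.5 fibro attempts per step — recruits arrive from the vasculature
side and migrate in, which is what reproduces the observed
near-implant depletion together with chemotaxis sweeping the vicinity
onto the implant. The four exploration scenarios draw candidate
pixels uniformly over the grid (the acceptance Hill terms, not the
placement, concentrate recruitment near the stimulus) with 1
macrophage and 3 fibro attempts per step.

## Counting geometry

The implant-vicinity counts use three 3 × 3 squares per side, stacked
outward along a 13-pixel line from the implant edge: a 2-pixel gap
(the smoothed skirt), the nearest square (rank 3), a 1-pixel gap,
rank 2, another gap, rank 1 — 2+3+1+3+1+3 = 13 pixels exactly. The
cross-line window is 3 pixels centred on the implant midline (an even
implant side has no exact midline pixel; the window sits at
floor(mid)−1 … floor(mid)+1). Four sides give twelve areas, four per
distance rank; macrophage counts pool all four states, fibroblast
counts are F1 only (a flag pools F0).

## What the validation scenarios emulate — and what they do not

The ensembles stand in for in-vitro macrophage cultures (secretion
validation) and a rodent subcutaneous implant (spatial validation).
They capture population-level kinetics, spatial redistribution and
mediator budgets. They do not model cell division, cell–biomaterial
adhesion (fibroblasts are "floating" cells; the implant has no
excluded volume for cells by default), granulocytes, angiogenesis, 3-D
geometry, or molecular pathway detail (SOCS is a single scalar, not a
JAK/STAT cascade). Passing tests therefore shows that the implemented
rules reproduce the published population readouts under the published
protocols, not that the parameters are transferable to other tissues
or stimuli.

## Numerical choices and degenerate inputs

* Threshold ties: a macrophage with both activations above 0.5 takes
  the larger; an exact tie is intermediate.
* Death boundary is inclusive (age ≥ lifespan).
* Truncated-normal lifespans redraw non-positive samples (≈ 4σ events
  for the printed mean/SD pairs).
* The diffusion-kernel constructor rejects parameter combinations with
  8·P > 1 rather than silently clamping.
* `k = 0` points are excluded from the power-law fit (with a count of
  exclusions in the report); a fit needs ≥ 2 usable points and
  positive N_c.
* Chemical "peak" stimuli centre on a pixel (`(n−1)//2`) so the
  stated maximum actually occurs on the lattice.
* Empty ensembles, out-of-bounds pixels, shape mismatches and invalid
  configs raise before any stepping; `validate()` returns the full
  violation list instead of stopping at the first.

## Reproduction scales

The validation protocols run at their published sizes: 25 runs × 6
days for each secretion condition, 5 runs × 7/28 days for the
biomaterial counts, single runs per (k, duration) for the chemotaxis
sweep. The whole acceptance script completes in about a minute on one
CPU; the test suite, including the ensemble-level tests, in about one
minute more.

## Known limitations

* **Chemotaxis scaling.** N_c grows monotonically with k, and its
  k = 0.02 values match the published curve, but the fitted power-law
  exponent averages ≈ 0.4 here versus the published ≈ 0.22. In this
  implementation cells keep making k-sensitive chemotactic moves
  around the secreted-PIM domes of the chronic M2/F1 colony for the
  whole run; the published exponent implies late-phase chemotaxis that
  is nearly k-independent (jammed or saturated). Restricting the
  chemoattractant to the stimulus-origin PIM reproduces the published
  exponent but abolishes the implant-ward sweep that empties the
  implant vicinity, and we prioritised the spatial validation. The
  discrepancy is confined to this one summary statistic.
* **Cross-talk magnitudes off the calibration targets.** AIM secreted
  under the PIM stimulus and PIM secreted under the AIM stimulus come
  out below their published values (≈ 0.8× and ≈ 0.1×); the four
  headline magnitudes (control PIM/AIM, PIM-stimulus PIM, AIM-stimulus
  AIM) are on target.
* **Scenario 1A plateaus late.** Without resident macrophages the
  acute wave is recruitment-limited; the total population reaches its
  maximum at the end of the 120-h window rather than peaking early and
  declining as it does with residents (1B).
* The biomaterial spatial quantities (fibroblast-increase percentage
  in particular) are ratios of five-run averages taken mid-transition
  and inherit a large seed-to-seed spread (± ~15 percentage points).
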