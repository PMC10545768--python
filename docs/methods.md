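# Methods

## Model structure

`segresim` couples a deterministic macroscopic chemostat to a stochastic
agent ensemble.

The macroscopic state (biomass X, limiting substrate S, secondary
nutrient/inducer I) follows the standard chemostat balance with Monod
growth. Inducer uptake is modelled as Monod in I and proportional to the ON
biomass fraction — a package choice, since inducer consumption kinetics are
not otherwise constrained. The feed can carry the inducer (`I_in > 0`) to represent chemostat
cultivations in which the alternative carbon source is co-fed, while
Segregostat scenarios feed glucose only and receive the inducer exclusively
through controller pulses.

Each of the ~10,000 agents (2,000 at desk scale) carries a phenotype bit, a
continuous GFP content and a relative size in [1, 2). One fixed-length step
applies, from start-of-step propensities (a tau-leap-style approximation):
Bernoulli phenotype flips with probability 1 − exp(−k·dt); explicit-Euler
GFP synthesis/decay floored at zero; exponential size growth with division
at size 2; Bernoulli washout with probability 1 − exp(−D·dt). The step
length divides the 12-min sampling interval and is chosen so every per-event
probability stays below 0.2 with margin; a dt-halving test keeps the
discretization honest (observables move by < 2 %).

Division splits GFP by a symmetric Beta(a, a) fraction with a = 50
(standard deviation ≈ 0.05 of the mother's content, comparable to binomial
partitioning of ~100 units); the partition noise is not pinned down
experimentally, so the concentration is a configurable default.

The ensemble is a constant-number Monte-Carlo representation of the
culture: uniform down-sampling to the target size when divisions double it,
whole-ensemble duplication when washout halves it. Absolute abundance lives
only in X; washout of the culture is declared from X < 10⁻⁴·X(0), never
from agent bookkeeping.

## Fitness-cost forms

Two cost laws are implemented:

* **linear** (package default): ON cells grow at mu·(1 − c). This is the
  plain "percent reduction of the uninduced growth rate" reading and is
  what every API example assumes.
* **inhibitory**: mu_on = mu·(1 − c)^(g/(g+K_i)). The burden compounds
  with the GFP load: a freshly switched cell grows almost normally, a
  saturated cell pays the full cost. K_i (default 10⁴ fluorescence units)
  is the half-burden GFP content.

The high-cost presets use the inhibitory form, for two reasons. First, it
matches the biology of expression burden: cost follows the amount of
heterologous protein, not the decision to express it. Second, it is what
makes the high-cost phenomenology reproducible at all: under a purely
linear cost the ON population settles at its GFP fixed point and stays
narrow (basal entropy ≲ 2.6 bits at every sub-washout cost), whereas
GFP-load-dependent selection removes high-load cells continuously and
sustains a broad distribution along the fluorescence axis (≈ 3.6–4 bits).
It also produces a sharp washout boundary: at c = 1 the ON state
contributes exactly zero growth whatever the load, while at c = 0.99 the
low-load growth channel keeps the culture alive — so complete washout
first appears above 99 % cost, robustly across seeds.

## Measurement model

A measurement samples 20,000 cells with replacement, adds an
autofluorescence background (default 100 units) and multiplies by a
unit-mean lognormal noise factor (CV 0.25 by default; 0.35 in the
wide-distribution presets), clamping to the seven-decade instrument range
[1, 10⁷]. Snapshots are binned into 50 log-spaced bins over exactly that
range, with clamping at both ends as instruments do.

Entropy is reported in bits. Cell flux between consecutive snapshots is
half the total variation of the count difference per minute, so a pure
relocation of N cells counts N moved cells; unequal event totals are
rescaled to the earlier snapshot before differencing. Note that the
resampling noise of 20,000-event snapshots puts an irreducible floor of
roughly 15–30 cells/min under F(t); bursts are therefore judged relative
to the median, not to zero.

## Regimes

`classify_regime` applies, in order: washout if the simulation flagged
extinction; bursty if any detected burst reaches 10× the baseline median
flux; constrained if the basal entropy is below 2.6 bits (between the
~2.2-bit and >3-bit preset groups); dispersed otherwise. Burst detection
thresholds F(t) at median + 5·MAD; within regime classification the first
12 h are excluded, because the forced batch-to-continuous activation
transient would otherwise register as one large spurious burst in every
run. All thresholds are configuration (`RegimeThresholds`), calibrated on
the presets rather than taken from measurements.

**Known limitation — spontaneous bursts.** With Monod-form switching
propensities and deterministic macro-coupling, the chemostat pins the
substrate near the growth-balance point and damps the large substrate
excursions that collective switching avalanches would require; across the
explored parameter space the open-loop system relaxes to a stable mixed
steady state. The high-cost presets therefore express their episodic
character as a broad, rapidly renewing distribution (classified dispersed)
rather than as discrete ≥10× flux bursts. The burst detector and the
bursty regime label are fully implemented and exercised on constructed
flux series; synthetic open-loop runs at this scale do not produce them
spontaneously.

## Control loop

Every sampling interval (12 min) the controller gates the snapshot at a
fluorescence threshold, compares the GFP-positive fraction with the
setpoint (maintain-ON pulses below 50 %; suppress-ON pulses above the
setpoint, 20 % for the sporulation preset), and injects its dose at the
start of the next interval. There is no refractory period — every
violating sample pulses — and sampling is treated as instantaneous. Ties
at the setpoint do not pulse. Pulse doses are free scenario parameters;
the high-cost glucose doses (tens of g/L) are calibration values that give
the feedback real authority over a strongly switching population, not
measured experimental doses.

Environment programs: constant dilution; the A-stat ramp
D(t) = D0 + 0.002·floor(t/2 h) h⁻¹; and dMSCC square waves implemented
with growth-chamber semantics — no washout (D = 0) and perfect media
exchange forcing S to the programmed value.

## Presets and the synthetic-data conditions

Presets run 60 h with measurements every 12 min and emulate the six
reporter classes; their kinetics are nominal, chosen once so that each
class reproduces its qualitative behaviour at desk scale (2,000 agents):

* `araB`/`lacZ`/`bolA` — fast, cheap, coordinated switching; basal entropy
  ≈ 2.2 bits; feedback changes mean entropy by < 0.3 bits.
* `glc3` — starvation-driven, inhibitory cost 0.96; basal entropy ≈ 3.9
  bits; glucose forcing removes ≈ 0.2–0.3 bits; sweeping only its cost
  from 90 to 100 % yields washout exactly and only at 100 %.
* `T7` — lactose-driven, inhibitory cost 0.9 at D = 0.5 h⁻¹, lactose
  co-fed in chemostat mode; ≈ 3.7 bits basal, ΔH ≈ +0.4 under forcing.
* `spoIIE` — famine-triggered, suppress-ON control at 20 % with glucose
  pulses at D = 0.1 h⁻¹; ≈ 3.4 bits basal, ΔH ≈ +0.2.

What the generator emulates: two-phenotype log-fluorescence distributions
over seven decades, their diversification transients, entrainment under
pulsed forcing, cost-dependent heterogeneity, and washout. What it does
not: scatter/size channels, doublets, spectral spillover, instrument drift,
multi-hour induction delays, plasmid-loss or mutation, and the discrete
burst trains seen in the high-cost experiments (see above). Passing tests
therefore validate the pipeline's arithmetic and the cost–heterogeneity–
controllability coupling within this model family, not instrument-level
realism.

## Numerical and interface choices

* One seeded `numpy` generator per run; identical scenario + seed gives
  byte-identical event tables and pulse logs.
* Entropy of empty distributions, empty snapshots, negative substrate,
  out-of-range costs and malformed files raise immediately with the
  offending location where applicable.
* Mutual information uses uniform weighting over stimulus levels (the
  experimental designs use equal replication):
  MI = H(pooled marginal) − mean conditional entropy. The alternative
  sum-then-subtract reading of the source description is not adopted; an
  optional pseudocount tames small-sample bias.
* Event tables, metric tables, pulse logs and sweep summaries are CSV;
  scenario configurations are YAML; a minimal read-only FCS 3.x reader
  (float and byte-aligned integer list mode, single channel) bridges real
  cytometry exports into the same pipeline.
* Desk-scale problem sizes — 2,000 agents, 60 h, 20,000-event snapshots,
  three seeds per reported mean — are the package's standard test
  conditions; entropy means vary by well under 0.02 bits between seeds at
  this scale.
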