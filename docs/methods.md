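# Methods

## Model and assumptions

The circuit is a static rate model: every neuron is described by its
steady-state firing rate as a function of log10 odour intensity `i`, with no
time-resolved or spiking dynamics.  The input layer has K excitatory
logistic units `exc_k` (shared slope `b` and asymptote 1, turning points
`a_k` spaced `a_step` apart and centred on zero) and one inhibitory logistic
unit `inh` with slope `b_inh < b` and asymptote `inh_max > 1`.  Each
intermediate neuron receives exactly one excitatory input and the shared
inhibitory input and applies a threshold-linear (rectifying) activation.
Because `exc_k` is steeper than `inh` and `inh` eventually exceeds every
weighted excitatory input (`inh_max > 1`), each intermediate response rises
and then returns to zero: a bell-shaped tuning curve with genuinely compact
support (the rectification produces exact zeros).

Homeostatic plasticity is a *static mean effect*.  We do not model how the
synaptic strength changes with each stimulus presentation; instead each
weight is set once from the sensitivity integral `s(a)` of its excitatory
channel over an exposure range `[c0, c1]` — a scalar proxy for how often
that channel was driven during the animal's pre-training odour experience.
The two scenarios (excitatory scaling `w_exc(a) = -α(s(a) - d)` with uniform
inhibition, and inhibitory scaling `w_inh(a) = -α̃ s(a)` with uniform
excitation) both weaken the contribution of sensitive channels.

Associative learning is a single reinforcement-gated Hebbian step on the
output synapses, starting from zero weights, with independent experiments
(weights reset between trainings).  No extinction, decay, repeated-trial
accumulation or appetitive reinforcement is modelled, and the innate
(untrained) behavioural pathway is outside the model: an untrained circuit
is silent at every test intensity.

## Default parameters: the peak-alignment construction

The qualitative constraints (`b > b_inh`, `inh_max > 1`, unit spacing of the
`a_k`) leave the parameter values open, and not every admissible choice
reproduces the intended behaviour — with a too-sensitive or too-strong
inhibitory unit, all but the most sensitive intermediate channel are silent
at every intensity.  The package therefore fixes its defaults by an explicit
construction rather than by hand-picked round numbers.

In the excitatory-scaling scenario we require each intermediate tuning curve
to peak exactly at its channel's turning point `a_k`.  Since `exc_k` has
slope `b` at `a_k`, stationarity there demands

    w_exc[k] · b = inh'(a_k),

and a positive peak value additionally requires `inh'(a)/inh(a) > 2b` at the
`a_k`, which pins the admissible regime: `b_inh > b/2` with the inhibitory
turning point well above the excitatory ones.  Given the anchors

| parameter | default | meaning |
|-----------|---------|---------|
| K         | 3       | number of channels |
| a_step    | 1.0     | channel spacing (log10 units) |
| b         | 1.0     | excitatory slope at turning point |
| a_inh     | 2.0     | inhibitory turning point |
| b_inh     | 0.6     | inhibitory slope (must exceed b/2 for alignment) |
| inh_max   | 2.5     | inhibitory asymptote |
| s_width   | 1.5     | width c1 − c0 of the exposure range |

the construction (`aligned_circuit`) solves for `c0` (by bracketed root
finding), `α` and `d` such that the homeostatic rule reproduces the aligned
weights exactly; with the defaults this gives `c0 ≈ 0.2715`, `c1 ≈ 1.7715`,
`α ≈ 0.6215`, `d ≈ 1.5057` and weights `w_exc ≈ (0.0045, 0.0486, 0.4575)`.
`α̃ ≈ 2.8405` applies the same alignment condition to the least sensitive
channel of the inhibitory-scaling scenario (the only channel for which it is
compatible with a positive response there).  Because each training intensity
then recruits essentially a single intermediate channel (the compact
supports barely overlap at the `a_k`), the recall curve peaks at the trained
intensity to within grid resolution.

Two structural consequences of this regime are worth stating plainly:

- Channel amplitudes are strongly graded.  Alignment forces the peak height
  of channel k to scale with `inh'(a_k)`, i.e. by a factor `e^{4 b_inh
  a_step}` (~11 here) per channel.  Weak-intensity memories are therefore
  *much* weaker than strong-intensity ones — qualitatively the right
  direction (weak training produces weak, broad conditioned behaviour), but
  more extreme than behavioural data suggest.
- The two homeostatic scenarios cannot both be made exactly specific with a
  single exposure range.  Exact alignment of the inhibitory scenario would
  need `s(a_k)` to fall geometrically (ratio `e^{4 b_inh}`) across the
  channels, but `s` is a tail integral of a log-concave function and hence
  log-concave: its consecutive ratios cannot increase the way the shared
  `[c0, c1]` (fixed by the excitatory construction) would require.  The
  defaults favour the excitatory scenario; the inhibitory one retains all
  qualitative signatures (non-nested crossing curves, peaks ordered with
  sensitivity, recall peaks that increase with training intensity and track
  it to within ~0.9 log units) but not grid-level specificity.

Similarly, without homeostasis the recall peaks of different trainings
cluster well below the spread of the training intensities (range ~0.5 vs 2
log units) but do not coincide exactly: a shared logistic inhibition cannot
pin the argmax of every weighted sum of nested bells to one grid point while
keeping all channels alive.  The qualitative contrast — specific with
homeostasis, unspecific without — is the robust statement.

All defaults are overridable through `CircuitSpec`, the YAML run config and
the CLI; the construction raises a clear error when asked for anchors
outside the alignment regime.

## Evaluation grid and peak extraction

The default grid is log10 intensity −6 … 6 in steps of 0.01, wide enough
that every default tuning curve is exactly zero at both ends.  Peaks are
grid argmaxima with ties broken toward the lowest intensity; FWHM is
measured on the connected region around the peak with linear interpolation
between grid points and is reported as undefined when the half-maximum level
is not crossed on both sides (e.g. monotonic curves).  Pointwise dominance
(nestedness) uses an absolute tolerance of 1e−12; dominance is transitive,
so a family is fully nested exactly when every pair is comparable.

Numerics: logistic responses are evaluated with `scipy.special.expit` and
the sensitivity integral with a softplus (`numpy.logaddexp`) formulation of
the closed form, so both are overflow-safe at extreme arguments; the closed
form agrees with adaptive quadrature to better than 1e−8.

## Behavioural pipeline and the synthetic generator

The CAS tables mimic the shape of published intensity-generalization data:
one training intensity per odour, several test intensities, a median
conditioned avoidance score per group.  Normalization divides test
intensities by the training intensity and CASs by the matched-intensity
value, so every curve passes through (1, 1) regardless of the sign
convention (fly CASs are negative for avoidance).  The Gaussian is fitted on
log10 of the intensity ratio by default — intensity is treated
logarithmically everywhere else in the model — with initial values A=1, μ=0,
σ=1 and σ bounded to (1e−3, 10); the linear-ratio axis is available via a
flag.  HWHM = σ√(2 ln 2) by definition.

The synthetic generator draws median CASs from a Gaussian tuning profile
(default HWHM 1.1 decades, a plausible fly-scale width; default peak CAS
−30) plus additive noise whose standard deviation is `noise_sd · |peak_cas|`
— i.e. `noise_sd` is noise on the peak-normalized scale, so the default 0.05
means 5% of the peak score.  It emulates the *shape* of behavioural
generalization curves, not their sampling structure: no per-animal
variability, no count-based preference indices, no odour identity effects.
Passing the recovery study therefore shows that the normalization + fitting
pipeline is unbiased and precise under Gaussian noise of realistic relative
magnitude, not that real behavioural HWHMs are estimated this well.

## Robustness sweep

The sweep re-runs the three-experiment battery over a parameter grid and
scores each point by the worst |recall peak − trained intensity|.  A point
passes when this score is ≤ 1.0 log unit — the channel spacing, i.e. the
memory is recalled closer to the trained intensity than to either
neighbouring channel.  Constraint-violating points (`b_inh ≥ b`,
`inh_max ≤ 1`, non-positive homeostatic `w_exc`) are recorded as skipped,
not failed.  The default design perturbs `b`, `b_inh` and `inh_max` by ±10%
(3 values each, 27 points per scenario); with it, 52% of excitatory-scaling
and 78% of inhibitory-scaling points pass.  The main fragility is the most
sensitive channel, whose aligned weight is small: perturbing `b_inh` can
silence it entirely.  The sweep is deterministic; repeated runs are
byte-identical.

## Known limitations

- Specificity is exact only at the channel centres `a_k`; training between
  channels recalls the nearest channel.  A finer `a_step` (more channels)
  refines the resolution — the motif scales in K.
- The inhibitory-scaling scenario and the no-homeostasis baseline carry the
  structural caveats described above.
- The sensitivity integral treats pre-training exposure as uniform over
  `[c0, c1]`; any non-uniform exposure history would reweight `s(a)`.
- Behavioural hypothesis testing (group comparisons on raw CAS data) is out
  of scope; the pipeline handles curve normalization and width estimation
  only.
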