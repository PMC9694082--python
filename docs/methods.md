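# Methods

`cav3perm` reimplements, as a tested pipeline, the quantitative analysis by
which sodium-permeable and calcium-selective Cav3 T-type channel variants
are distinguished in whole-cell voltage clamp: Na⁺-for-NMDG⁺ fold-change
assays, bi-ionic reversal-potential permeametry with the Fatt–Ginsborg
relation, monoexponential kinetics, and the accompanying group statistics.
Because the underlying per-cell recordings of such studies are not published,
every stage is validated against a synthetic recording generator with known
ground truth. This note documents the models, the tunable parameters, the
numerical choices, and what the validation does and does not establish.

## The synthetic recording model

Each simulated sweep is

I(t) = m(t)·h(t) · Σᵢ I_GHK,ᵢ(V) + g_leak·(V(t) − E_leak) + ε(t)

* **Open-channel current.** Constant-field (Goldman–Hodgkin–Katz) flux per
  ion species: I = P·z·x·([C]ᵢₙ − [C]ₒᵤₜ e^(−x))/(1 − e^(−x)), with
  x = zVF/RT and the removable singularity at V = 0 evaluated by its limit
  P·z·([C]ᵢₙ − [C]ₒᵤₜ). P is a lumped permeability × membrane-area scale
  (pA/mM); only permeability *ratios* are meaningful, matching how the field
  reports selectivity. Current is positive outward. Because this is exactly
  the constant-field model, the bi-ionic reversal potential of a simulated
  cell satisfies the Fatt–Ginsborg relation analytically — the simulator and
  the analysis equation are two views of one model, which is what makes
  closed-form cross-checks possible.
* **Gating.** Hodgkin–Huxley m·h: Boltzmann steady states
  m∞ = 1/(1+e^((V½−V)/k)) (activation) and the mirrored form for
  inactivation, each relaxing exponentially from the holding steady state
  with a voltage-dependent time constant (sigmoid in V, slower at
  hyperpolarized potentials). Single activation power; no Markov states.
* **Leak and noise.** Ohmic leak in nS (nS·mV = pA) and additive i.i.d.
  Gaussian noise per sample. All stochastic draws derive from
  (seed, sweep index) via NumPy `SeedSequence`, so a recording is
  bit-reproducible from its metadata.

**Protocols.** Default protocol: hold −110 mV, 300 ms steps, −80…+80 mV in
5 mV increments, 10 kHz sampling, 10 ms pre-step baseline; capacitive
transients, series-resistance error and liquid-junction potentials are not
modeled, and each sweep starts from steady state at holding (inter-sweep
recovery is assumed complete). The *analysis* protocols extend the step
family below −80 mV (to −110 mV for preset studies, −140 mV for the
recovery study) so that sweeps exist where a T-type conductance is closed:
those subthreshold sweeps are what the offline linear leak fit uses.

**Solutions.** Two configurations mirror standard practice: the fold-change
configuration (external 2 mM Ca²⁺ + 135 mM NMDG⁺ or Na⁺ + 25 mM TEA⁺,
internal 110 mM Cs⁺) and the bi-ionic configuration (external 4 mM Ca²⁺ +
155 mM TEA⁺, internal 100 mM Li⁺/Na⁺/K⁺/Cs⁺). NMDG⁺ and TEA⁺ are impermeant
by default; `p_nmdg` injects a small NMDG⁺ permeability for sensitivity
checks. Temperature defaults to 295.15 K (22 °C, RT/F ≈ 25.43 mV) and is a
required metadata field: the Fatt–Ginsborg ratio depends on RT/F, so every
permeability result records the temperature it assumed.

**Presets.** Named presets ("12a-like", "12b-like", the two point-mutant
swaps, "hCav3.2-like", "D-to-N-like") differ in their P_Ca/P_X ratios
(and in gating speed as flavour), chosen once so that the qualitative
orderings of the biology hold: turret-lysine variants are sodium-permeable
(small P_Ca/P_Na, large Na-vs-NMDG fold change, hyperpolarized bi-ionic
reversal), alanine variants and the human channel are calcium-selective,
and the selectivity-filter D→N mutant is intermediate. Published population
fold-change statistics are attached to the presets as reference annotations
only; they are not fitting targets, and the simulator makes no claim to
reproduce their magnitudes (a constant-field pore cannot express the
asymmetric inward-competition effects that make the real fold changes as
large as reported). Activation midpoints were tuned once so the simulated
peak I–V falls near −40 mV (molluscan presets) and −30 mV (human preset);
this is documentation of the preset, not an assertion about real channels.

## Preprocessing

* **Gaussian filter.** Unit-area Gaussian kernel with the −3 dB convention:
  σ_t = √(ln 2)/(2π f_c), so the amplitude response at the cutoff is exactly
  1/√2. Kernel truncated at ±4σ_t, reflection padding, output length equals
  input length (via `scipy.ndimage.gaussian_filter1d`). The cutoff
  convention is recorded in the processing history because acquisition
  suites do not agree on one.
* **Leak subtraction.** Ordinary least squares of the steady-state current
  (mean over the final 5 ms of the step) against step voltage over
  subthreshold sweeps (default −110…−90 mV), then subtraction of
  g·(V_cmd(t) − E_leak) using the commanded voltage at each sample. P/N
  subtraction is not implemented. Both transforms are linear, so their
  order is irrelevant except within one kernel width of the step edge.

A practical caveat the test suite quantifies: the leak line is fitted far
from the voltages where it is applied, so per-cell noise in the subthreshold
fit propagates as an amplified offset at the reversal voltages. The recovery
study uses steps down to −140 mV precisely to lengthen that lever arm.

## Peak I–V and reversal potentials

Peaks are extrema of the conditioned trace within the step window, excluding
the first 2 ms after step onset (capacitive guard; configurable). Polarity
`auto` takes the larger absolute deviation from zero. An alternative
`isochronal` measure reads every sweep at the peak latency of the
largest-amplitude sweep (mean over ±1 ms): near the reversal a sweep is
essentially flat, and its own noise extremum is a biased estimate of nothing;
the isochronal reading is the standard way around that.

The reversal potential is extrapolated from the linear limbs of the peak
I–V: ordinary least squares through the `n_below` last negative-current and
`n_above` first positive-current points around the sign change (default 2+2;
E_rev = −intercept/slope, slope reported as the linear conductance). The
sign change is located by minimizing the magnitude-weighted sign
misclassification, so near-zero points whose sign is set by noise cannot
move the crossing. With 5 mV steps the 2+2 OLS carries a small curvature
bias (~0.1–0.4 mV depending on where the reversal sits); interpolating the
bracketing pair alone (1+1) removes it at the cost of noise averaging —
bias-limited analyses should use 1+1, variance-limited ones 2+2.

The Fatt–Ginsborg relation converts E_rev to a permeability ratio:

P_Ca/P_X = ([X]ᵢₙ / (4[Ca]ₒᵤₜ)) · u(u+1),  u = e^(E_rev·F/RT),

with the closed-form inverse u = (−1+√(1+16[Ca]ₒᵤₜ·r/[X]ᵢₙ))/2 available for
round-trip checks. Concentrations are nominal (no activity coefficients).
Fold change is computed per cell as |I_Na|/|I_NMDG| at the preset's test
potential and then averaged (mean ± SEM), not as a ratio of group means.

## The parameter-recovery oracle

End-to-end validation (simulate → filter → leak-subtract → peak I–V →
E_rev → ratio) uses a purpose-built oracle channel rather than a display
preset: activation is a cliff-like Boltzmann (V½ −84 mV, slope 1.2 mV) that
saturates just below the bi-ionic reversal band and is fully closed below
−100 mV, and inactivation is T-type-placed but very slow (τ = 150 ms), so
peaks occur within a few ms at every voltage. This isolates what the
recovery test is meant to check — the analysis chain — from a separate,
real phenomenon: when voltage-dependent gating overlaps the reversal band,
it multiplies the local I–V and biases the linear extrapolation by several
mV. Display presets have exactly that overlap, as real T-type channels do;
their reversal estimates are accurate to a few percent, not to the 2% the
oracle channel achieves. Under the oracle conditions, noiseless recovery is
within 0.8% (2+2) or 0.35% (1+1) for P_Ca/P_X from 0.5 to 60.

The noisy arm of the recovery study uses noise_sd = 5% of the cell's peak
current at the −40 mV test step, 20 cells, the isochronal measure and 1+1
interpolation, and checks that the t-based 95% confidence interval of the
mean recovered ratio covers the truth. Because the ratio is a convex
(exponential) transform of E_rev, the mean recovered ratio carries a small
positive skew bias (~1%); empirical coverage is therefore close to, but not
exactly, nominal — across seeds roughly nine of ten repetitions of the whole
study cover.

## Kinetics

Monoexponential fits I(t) = A·e^(−(t−t₀)/τ) + C by Levenberg–Marquardt on
(A, log τ, C), initialized from a log-linear regression on |I − Ĉ| with Ĉ
the terminal mean. Relative tolerance 1e-8, at most 500 function
evaluations; non-convergence is reported (`converged=False`), never
silently dropped; flat traces raise a degenerate-fit error. Default
windows: [peak time, step end] for inactivation, [onset + guard, peak time]
for activation; deactivation windows must be explicit. Noiseless exact-model
recovery is exact to float precision; at SNR 20 with 3000 samples the median
τ error over 100 noise draws is ~1%.

## Statistics

Mean ± SEM (n−1 denominator), pooled or Welch two-sample t, fixed-effects
one-way ANOVA from between/within sums of squares, and Tukey–Kramer HSD
with q = |Δmean|/√(MS_w(1/nᵢ+1/nⱼ)/2) and the adjusted p from the
studentized-range distribution (scipy's quadrature; accurate well below the
1e-4 this module promises). Unequal n uses the Kramer form. Significance is
reported at 0.05. No nonparametric or repeated-measures designs.

## Selectivity-filter classification

Input is a curated alignment plus an explicit role map (1-based columns for
the four ring residues, the Domain II +1 residue, and the Domain II turret
position) — the package never aligns sequences, because a silently different
alignment would silently change role columns. Classification precedence:
ring lysine in Domain II/III → sodium-selective (Nav1-like); DEEA ring →
non-selective (Nav2-like); all-acidic ring with +1 aspartate → calcium-
selective unless a turret lysine neutralizes it (sodium-permeable,
turret-lysine); all-acidic ring with +1 asparagine → sodium-permeable
(EN-type); anything else unclassified. Gaps at required roles yield
`unclassified` with a reason rather than an exception. Cysteines are counted
per extracellular loop interval; disulfide pairing is not predicted.

The packaged panel (`data/channel_panel_synthetic.fasta`) is a *constructed*
alignment encoding only the classification-relevant residues of a
representative channel set; it is explicitly not real sequence data, and
role columns for real sequences must come from the user's curated alignment.

## What passing tests do and do not show

The generator produces exactly the model family the analysis assumes
(constant-field pore, first-order gating, ohmic leak, white noise). Passing
recovery tests therefore demonstrates the correctness and numerical
stability of the analysis chain, not its robustness to the things real
recordings add: series-resistance error, capacitive transients, drifting
seals, channel rundown, non-GHK pore behaviour (anomalous mole fraction,
saturation), and the asymmetric ion competition that makes measured fold
changes larger than bi-ionic ratios predict. Problem sizes throughout
(sweep counts, cell counts, noise-draw counts) were chosen as the smallest
that make the statistical assertions stable.
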