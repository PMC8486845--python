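# Methods

`zipperjunction` models and analyses single-molecule junctions in which a
DNA duplex clamps the gap between an STM tip and a gold surface in the
*zipper* configuration: both thiol linkers sit at the same duplex end, the
helix axis lies perpendicular to the gap, and mechanical failure of the
junction proceeds by unzipping base pairs from the tethered end rather than
by breaking an Au–S bond. This note records the models, the defaults and
the numerical choices, and what the synthetic data do and do not emulate.

## Synthetic break-junction traces

A conductance–displacement (G–z) trace is generated piecewise linearly in
(z, ln G):

1. a fast approach decay at `beta2` from `start_conductance`
   (100 mG₀) down to the plateau entry;
2. a molecular plateau of drawn length L with slope `-beta1`, geometrically
   centred on `plateau_conductance` so that the dwell inside a symmetric
   conductance band equals L up to sampling discretization (±2 samples:
   one band-entry sample plus increment rounding);
3. an abrupt rupture drop (factor 0.4) — the junction breaks faster than
   the sampling interval — followed by the tunnelling decay at `beta2`
   down to the noise floor (10⁻⁶·⁵ G₀) and a 0.2 nm flat tail.

Decay constants follow G ∝ exp(−βz) with z in Å (natural log); the
90-mer preset uses β₁ = 0.27 Å⁻¹, β₂ = 2.0 Å⁻¹, plateau 1.9 mG₀; the
10-mer preset plateau is 0.15 mG₀ (its decay constants default to the
90-mer values pending separate data); the bare preset decays at 2.2 Å⁻¹
with no plateau. Sampling is 20 kHz at 31 nm/s tip velocity
(dz = 1.55 pm). Noise is multiplicative in conductance: Gaussian in
log₁₀ G with 0.1 decades sd, chosen to broaden the 2D histograms visibly
without destroying plateau detectability; conductance is clipped to
[noise floor, start]. Plateau lengths are log-normal with arithmetic mean
0.15 nm (90-mer) or 0.07 nm (10-mer) and 50 % coefficient of variation,
and a junction forms on 80 % of approaches (`plateau_probability`).

What the generator does **not** emulate: Au point-contact rupture and
snap-back above 50 mG₀, 1/f and drift noise, multi-molecule plateaus,
sequence-dependent conductance. Tests passing on this generator therefore
validate the *analysis chain* (origin convention, filtering, fitting)
under a controlled noise model, not performance on raw instrument data.

## Trace analysis

**Origin.** z = 0 is placed at the first sample with G < 50 mG₀; earlier
samples keep negative z. Traces that never cross 50 mG₀ are flagged and
excluded from ensemble statistics rather than force-originated. The
operation is idempotent.

**Plateau filter.** Presence of a plateau is judged per trace from its own
log₁₀ G histogram: 0.1-decade bins over [−6, −1] (the upper edge of the
noise floor region is excluded so the flat tail never counts as a
plateau), with the trace median-filtered over 11 samples first. A plateau
is declared when the best bin's occupancy, converted to displacement via
the sampling step, reaches `min_plateau_nm` = 0.05 nm. Two half-offset bin
grids are evaluated so a plateau straddling a bin edge is not split; with
one grid the worst-case alignment halves the occupancy. A mathematically
exact fast exponential (β ≳ 0.5 Å⁻¹) can never reach the occupancy
threshold; a noiseless plateau longer than ~0.1 nm always does.

**Fit windows.** The β₁ window is refined from the histogram band by a
local-slope criterion: sliding least-squares slopes over 61 samples,
plateau where |slope| < 1.0 Å⁻¹, longest run, 2 samples trimmed per edge.
The 61-sample span makes the slope estimator's noise sd (~0.11 Å⁻¹ at
default noise) small against the threshold, so window boundaries are set
by the trace shape rather than by noise — a shorter span was found to
condition the retained samples on their own fluctuations and attenuate
the fitted β₁ by ~7 %. Because a slope window overlapping the fast
segments always exceeds the threshold, the refined window sits strictly
inside the plateau and noise-free fits recover the generator values to
machine precision. The β₂ window starts at the first sample whose
smoothed log₁₀ G has fallen 0.45 decades below the band centre (i.e.
after the rupture drop) and ends before the first sample at the noise
floor; floor-clipped samples are excluded so the clamp cannot bias the
slope. Fits are ordinary least squares on ln G — the generator noise is
log-Gaussian, so OLS is maximum likelihood; a robust alternative can be
swapped in through the config.

**Peak estimation.** The ensemble log₁₀ G histogram over a preset fit
range ([−3.1, −2.35] for the 90-mer band, [−4.25, −3.45] for the 10-mer)
is fitted with a Gaussian plus constant offset; the offset absorbs the
tunnelling-decay background. Because the decay background is one-sided
(above the plateau), fitted centres run ~5 % high of the preset value —
well inside the ±10 % recovery target; a degenerate single-bin histogram
returns that bin's centre with zero width, and an empty one raises.

## Transition voltage spectroscopy

Sweeps span ±1.1 V in 100 samples (a 5 ms sweep at 20 kHz). The molecular
high-conductance state uses the symmetric single-level model
I(V) = (2e/h)·Γ·[atan((eV/2−ε₀)/Γ) + atan((eV/2+ε₀)/Γ)], which is odd in
V and has an interior Fowler–Nordheim minimum whose position is tuned
through ε₀ by a brute-force scan against the same extraction pipeline
used for data (default: minimum at 0.4 V with Γ = 0.05 eV → ε₀ ≈ 0.334 eV).
The tunnelling low state is I = aV + bV³ with a = 1.0×10⁻¹⁰ A/V and
b = 1.2×10⁻¹⁰ A/V³ (about 10⁴× lower low-bias conductance, FN minimum
near 0.9 V). Noise is log-normal on |I| (0.05 decades), preserving sign
and I(0) = 0.

Classification uses the mean |I/V| over 0.05–0.15 V, log-transformed and
split by deterministic 1D two-means (centres initialized at min/max);
ensembles whose cluster centres differ by < 0.5 decades are treated as a
single population and labelled by the configured fallback. FN spectra
exclude |V| < 0.1 V (the 1/V singularity); V_trans is the |V| at the
interior minimum after a 5-point centred moving average, with boundary
minima reported as undefined. Polarities are analysed separately and
pooled by absolute value — the generator is bias-symmetric, so pooling is
lossless, and per-polarity values remain available.

## Self-restoration statistics

The dwell length of a trace is the summed displacement of samples inside
the plateau band (1.4–2.4 mG₀ for the 90-mer, 0.14–0.16 mG₀ for the
10-mer); a junction counts as formed when the dwell reaches the plateau
threshold (0.060 nm / 0.028 nm), with ties formed (the tie rule is a
package choice). The formation series is summarized by p(form), the joint
probability that adjacent traces both form, and their ratio
p_joint/p_form² (1 under independence). Significance comes from a
two-sided permutation test (999 shuffles, add-one corrected) — an
exchangeability null chosen because the exact reference construction for
this statistic is not fixed by convention; the statistic and null are
this package's reconstruction and are documented as such. The longest
all-true run times the junction's survival: at the default per-trace
period (30 nm pull at 31 nm/s plus a 0.3 s hybridization wait ≈ 1.27 s),
a 78-trace run lasts ≈ 100 s. Consecutive-trace series are generated
either i.i.d. (Bernoulli p_form), as a two-state Markov chain with
stationary probability p_form and persistence P(formed→formed) =
p_persist (defaults 0.8/0.95 for the persistent preset), or driven by the
zipper simulator.

## The 1D zipper model

The duplex state is reduced to the fork coordinate n_open — base pairs
unzipped from the tethered end. This is deliberate: the phenomena of
interest (partial unzip under a 30 nm pull, spontaneous reannealing,
pN-scale forces) live in this coordinate, and the reduction is testable
against exact enumeration.

**Energetics.** Opening costs come from the embedded unified
dinucleotide nearest-neighbour ΔH/ΔS set (SantaLucia 1998 unified
parameters, 1 M NaCl reference; salt corrections are deliberately
omitted, consistent with simulating ambient, non-electrolyte conditions).
At 300 K every step favours the closed state (costs 0.8–3.2 kcal/mol).
Per-pair costs distribute each step half to each flanking pair, so the
total equals the plain step sum and is reverse-complement invariant;
duplex initiation terms are kept out of the fork ladder (they are
destabilizing at 300 K and would make terminal costs negative) but are
available in `duplex_free_energy`.

**Mechanics.** At fixed tip height z the tether force solves
slack + 2f/k + (2·n_open + linker_nt)·x_ss(f) = z, with x_ss the
freely-jointed-chain extension per nucleotide (contour 0.63 nm/nt, Kuhn
length 1.5 nm), two 8.5 N/m springs in series, a 2 nm slack for the fixed
duplex-end geometry, and `linker_nt` = 4 nucleotide-equivalents of
always-present compliance representing the propanethiol linkers and
terminal-base geometry. Without that term the model's load path is rigid
at n_open = 0 (series stiffness 4250 pN/nm) and transient re-closures of
the terminal pair against a taut chain produce 100–400 pN single-
microstate force spikes; the linker term caps them at the tens-of-pN
scale. Setting `linker_nt = 0` recovers the pure Hookean spring limit
f = (k/2)(z − slack). The root is bracketed and solved to < 10⁻⁹ nm
residual. The mechanical free energy Φ(n, z) is evaluated exactly at the
equilibrium force: spring energy f²/k plus the FJC Helmholtz energy per
nucleotide via the Legendre transform f·x + g(f), with
g(f) = −(c/b)kT ln(sinh u/u), u = fb/kT.

**Kinetics.** A Metropolis chain proposes ±1 fork moves at a fixed
attempt rate (10⁶ s⁻¹) with acceptance exp(−ΔE/kT), where
E(n) = Σ pair costs + Φ(n, z); out-of-range proposals are rejected
(reflecting boundaries). At frozen z the stationary law is exactly the
Boltzmann distribution of the enumerated E(n) — verified against
enumeration on small duplexes. During pull/return the tip advances on a
0.01 nm grid with Φ pre-tabulated per (n, z) by vectorized bisection
(quasi-static discretization; the pull velocity is represented exactly up
to rounding of attempts per grid step). The default 30 nm pull at
31 nm/s therefore takes ~10⁶ attempts. The recorded per-frame force is
the time average over the sampling stride, i.e. the bandwidth-limited
observable a force probe would report; instantaneous microstate forces
fluctuate faster than any measurement. Runs terminate early on strand
separation (n_open = n_bp under tension) or if the force exceeds the
Au–S rupture threshold (1.5 nN default — never reached in practice: the
unzipping pathway caps the load at tens of pN).

The unzip-force plateau (mean force over frames in which the fork
advanced) sits at ~14 pN for a random 50 % GC 90-mer, consistent with the
fixed point of 2·g_ss(f) = ΔG_bp (≈ 13 pN for poly-A, ≈ 15.5 pN at mean
random-sequence stability) and with the 10–50 pN range expected for DNA
unzipping. The force is weakly (logarithmically) loading-rate dependent;
the acceptance window is wide enough to absorb this. Under the 30 nm
pull a 90-bp duplex opens ~30 pairs and retains a partial duplex through
the hold; returning the tip (or releasing it — spring coupling set to
zero) lets the duplex reanneal completely. A 10-bp duplex, whose full
single-strand reach (~17 nm including slack) is far below the pull
distance, always separates.

**Not modelled:** 3D structure, grooves, persistence length, base-pair
distances (the per-pair open/closed record stands in for them),
electrostatics, mismatched or register-shifted rehybridization pathways,
and hybridization of fresh strands from solution (the simulator-driven
series mode re-forms lost junctions with probability p_form per approach
as a stand-in).

## Problem sizes and determinism

Default study sizes: 2,000-trace ensembles for peak recovery, 200 sweeps
for V_trans, 700-trace series for restoration statistics, 10–20 seeds for
simulator ensembles, 10⁶ attempts for equilibrium checks. Every stochastic
component takes an explicit seed (numpy `default_rng`) and is
bit-reproducible for a fixed seed and stride. The acceptance script
derives all per-run seeds from its single `--seed` argument.

## Known limitations

* The plateau filter reconstructs a histogram-occupancy rule whose exact
  published form is not fixed here; it is parameterized (bin width,
  range, threshold, smoothing) so alternatives can be dialled in.
* Slow exponential decays (β ≲ 0.5 Å⁻¹) are indistinguishable from
  plateaus by any per-trace histogram criterion at the default bin width.
* The 10-mer preset's decay constants and all plateau-length
  distributions are placeholders pending separate measurements.
* Whether experimental V_trans means pool both polarities is unknown;
  this package pools by |V| and also reports per-polarity values.
* The zipper model's spring attachment geometry (rest lengths, slack) is
  a reconstruction; slack and linker compliance are explicit parameters.
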