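# Methods

## Gating model and electrophysiology pipeline

The whole-cell K⁺ conductance is modelled as a single homogeneous
population of two-state voltage-gated channels. The steady-state specific
conductance follows a Boltzmann function of membrane potential,

G′(E) = G′_b + (G′_max − G′_b)·P_O(E),  P_O(E) = 1/(1 + exp(z·F·(E − E₁∕₂)/(R·T))),

with z > 0 so that the open fraction *decreases* with depolarization — the
sign convention was pinned by checking that the group-mean parameter sets
reproduce the known open fractions at the −23 mV holding potential
(89% for BSC-type, 66% for MC-type, thermal voltage 25.7 mV). The net
maximal conductance G′_max_net = G′_max − G′_b is reported as an exact
derived quantity.

**Simulator.** The gate relaxes first-order toward its steady state,
dp/dt = (p∞(E) − p)/τ, integrated in closed form because the command
voltage is piecewise constant during the 1 s pre-pulse. τ = 100 ms by
default and voltage-independent; the real activation kinetics of these
channels are not characterized here, and τ only needs to satisfy
τ ≫ ramp duration (30 ms) for the frozen-gate assumption. A recording
simulated with a ramp slower than τ carries a `ramp_slower_than_gate`
warning flag. During the ramp p is frozen exactly, so ramp currents are
exactly linear in voltage at zero noise. Whole-cell current is
I = πd²·G′·(E − E_rev) with the sphere-surface-area assumption (area
= π d², d the protoplast diameter: 27.4 µm BSC-like, 43.5 µm MC-like
defaults). Default Gaussian current noise is 5 pA per sample, a typical
low-noise whole-cell level at ~1 kHz filtering. Capacitive transients and
series-resistance error are not simulated (they are compensated at the
amplifier in practice); a mixture of channel populations is likewise out
of scope.

**Protocol.** Fifteen 1 s square pulses from +120 to −160 mV in −20 mV
steps, each followed by a 30 ms ramp from +70 to −70 mV, sampled at
2 kHz, nominal holding 0 mV. Command voltages are stored nominal; the
analysis adds the bath-specific liquid junction potential (−23 mV low-K⁺,
−14 mV 30 mM-K⁺) to every voltage before use, so nominal 0 mV holding
analyses as −23 mV. Inter-sweep intervals are not simulated: the gate is
re-initialized at the holding-potential steady state each sweep.

**Conductance extraction.** Per sweep, the ordinary-least-squares slope
of current vs corrected ramp voltage is the membrane conductance in nS
(pA/mV); the first and last 2 ms of each ramp are discarded
(clamp settling; configurable). Ramps with R² < 0.99 are flagged and
excluded from fitting. G′ = G/area (nS → mS is 1e-6), keyed by the
corrected pre-pulse potential.

**Boltzmann fitting.** Trust-region nonlinear least squares
(scipy `curve_fit`) on the unflagged G–V points (≥ 6 required),
parameterized as (G′_b, G′_net, E₁∕₂, z) with bounds G′_b ≥ 0, G′_net ≥ 0,
0 < z ≤ 5, initialized at G′_b = min(G′), G′_net = range(G′), E₁∕₂ = the
voltage of mid-conductance, z = 1; optimizer tolerances 1e-14 so
noiseless self-consistency recoveries reach ~1e-6 relative error. A flat
curve or optimizer failure yields a non-converged fit object (flagged,
never NaN-crashing); non-converged cells are excluded from group
averaging with a log message. Fits are averaged per cell type
(fit-then-average), never the reverse.

**Reversal potential.** Each ramp's I–V line is fitted; all pairwise
intersection voltages among ramps whose slope difference exceeds 5% of
the largest slope magnitude are collected (near-parallel pairs give
unstable crossings), and E_rev is their median, with the median absolute
deviation as a dispersion diagnostic. At least 3 ramps are required; all
slopes equal is an error (no crossover exists).

**Group statistics.** Means ± SE per cell type and two-sided Welch
(unequal-variance) t-tests per parameter. Welch is a deliberate choice
over the pooled test: the two cohorts have unequal sizes and there is no
reason to assume equal variances.

**Nernst and flux direction.** E_X = (RT/zF)·ln(c_out/c_in), default
T = 295.15 K (22 °C). Relative K⁺ flux at potential E_M is
−[G′_b + G′_max_net·P_O(E_M)]·(E_M − E_K): positive = influx
(E_M < E_K), negative = efflux. With 5 mM bath and 140 mM pipette K⁺
this gives E_K ≈ −84.7 mV.

## Expression analysis

The pipeline starts at a normalized genes × samples log₂ expression
matrix (log₂(NREL)); array preprocessing is out of scope. "Expressed"
means the per-type *mean* over replicates ≥ 2.0 — a per-replicate rule
would also be defensible, but the per-type summary is what a per-type
Venn diagram implies, and the choice is documented here once.
Differential expression uses a pooled-variance two-sample t-test per gene
(identical to two-group one-way ANOVA), a signed linear fold change
2^Δmean (reported as −1/ratio below 1), and the gates |FC| ≥ 1.5
(inclusive, with a 1e-9 absolute guard so a gene exactly on the boundary
is not dropped by float rounding of 2^Δ) and raw P < 0.05. No
multiple-testing correction is applied by design — the filter is a
reproduction of a raw-P screening rule — but `correction="bh"` adds
Benjamini–Hochberg adjusted P-values for users who want them. Genes with
zero variance in both groups get a fallback P (0 if the means differ,
1 otherwise) and a `p_fallback` flag.

Transporter classification crosses the P ≤ 0.05 differential set (no
fold-change restriction) with high expression (mean log₂ ≥ 3.5) per cell
type: group A high in the second type only, group B high in the first
type only, group C high in both; the groups are disjoint subsets of the
differential transporter set by construction.

Enrichment is a one-tailed hypergeometric over-representation test per
flat category label against the full background — a stand-in for
web-tool enrichment (modified Fisher / EASE scores); no GO DAG traversal
is performed. P-values are exact and are verified against exhaustive
subset enumeration for small backgrounds in the test suite.

**Generator.** Per-gene baselines ~ N(3.0, 1.5²) on the log₂ scale
(median expression ≈ expression threshold, a realistic microarray-like
spread), replicate noise sd 0.2, three replicates per cell type, spiked
genes shifted by their assigned log₂ fold change in the first cell type.
Defaults: 1000 genes, 50 spiked at |log₂FC| = 1.5. The generator does not
emulate probe-level effects, variance–mean dependence, or correlated
genes, so passing tests demonstrate the filter logic, not robustness to
real microarray noise structure.

## Ratiometric imaging

Protoplast membranes are rendered/segmented as rings. Segmentation:
global Otsu threshold on the 531 nm-excitation image → connected
components (≥ 30 px) → circle fit per component (centroid + mean radial
pixel distance) → annulus of 3 px (default) centred on the fitted rim.
Rings touching the image border are flagged `edge` and excluded by
default. Background per channel is the mean of the dimmest 20% of
non-cell pixels; no flat-field correction.

The per-protoplast ratio is mean(438 − bg₄₃₈)/mean(531 − bg₅₃₁) over the
annulus — the ratio of ROI means, not the mean of per-pixel ratios, which
is noisier because per-pixel denominators near background blow up.
Saturated pixels are excluded; a fully saturated annulus or non-positive
denominator yields an invalid (NaN) result. With exact backgrounds the
ratio is invariant to a common gain on both channels. The 438 nm channel
is the numerator, so hyperpolarization (more negative potential) gives a
smaller ratio.

**Generator.** The assigned-potential → ratio map is linear
(ratio = 1.8 + 0.01·E_M per mV, so −100 mV → 0.8 and −60 mV → 1.2),
consistent with the approximately linear small-signal response of
fast-response potentiometric dyes; no absolute millivolt calibration is
attempted anywhere in the package. 16-bit images, ring amplitude 20 000
counts over a 500-count background, Gaussian noise sd 50 per channel.
Chloroplast autofluorescence and dye-loading variability are not
emulated.

## Pipeline and determinism

`run_pipeline(RunConfig(...), outdir)` executes the three stages with
cohort sizes 8 BSC / 4 MC recordings, a 1000-gene matrix and 12
protoplasts per imaging group by default, writing per-stage TSV tables, a
combined `summary.json` and a `manifest.json` with the config and
package version. All randomness flows from the single config seed through
`numpy.random.default_rng` / `SeedSequence`, so a config fully determines
every output byte. A bath without a liquid-junction-potential entry fails
validation before any computation.

## Known limitations

- Single-channel analysis, activation-kinetics (τ) estimation and
  channel-identity inference are out of scope.
- The Boltzmann fit assumes one homogeneous channel population; real
  whole-cell currents may superpose differently-modified channel
  subpopulations, which shifts the apparent E₁∕₂ and flattens z.
- The E_rev estimator assumes the instantaneous ramp I–V is linear
  (ohmic open channels); strong rectification within the ramp span would
  bias it.
- The expression module treats categories as flat labels and P-values as
  raw; its counts are only as meaningful as those conventions.
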