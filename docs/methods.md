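# Methods

This note records the models, the parameter choices that matter, and the
limits of what the synthetic test bed can show. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Tissue model

The sheet obeys the monodomain reaction–diffusion equation with
two-variable Aliev–Panfilov kinetics,

    du/dt = D ∇²u + [k u (1 − u)(u − a) − u v] / τ
    dv/dt = (ε0 + μ1 v / (u + μ2)) · [−v − k u (u − a − 1)] / τ,

where `u` is the dimensionless action potential and `v` the recovery
variable. This phenomenological model reproduces the features the mapping
method actually probes — restitution, spiral-wave reentry, conduction
block — without the stiffness of biophysically detailed ionic models; the
entropy mapping under test is agnostic to the ionic model that produces
the activation patterns.

Parameters (defaults):

| parameter | value | role |
|---|---|---|
| k | 8 | sharpness of the excitation nonlinearity |
| a | 0.15 (stable/paced), 0.18 (meandering) | excitation threshold; lower = more excitable |
| ε0, μ1, μ2 | 0.002, 0.2, 0.3 | recovery dynamics / restitution |
| τ | 8 ms (5 ms for the meandering scenario) | time scale, ms per model time unit |
| D | 0.02 mm²/ms | isotropic diffusion |
| dx | 0.25 mm | grid step; 128 × 128 cells = 32 × 32 mm sheet |
| dt | 0.05 ms (production), 0.1 ms (quick runs) | explicit-Euler step |

With these values a paced plane wave conducts at ≈ 0.07 mm/ms with an
action-potential duration of ≈ 190 ms (wavelength ≈ 13 mm, so reentry
fits the sheet), and the stable spiral rotates with a ≈ 270 ms cycle —
slow atrial-flutter-like rates, adequate for the mapping question. The
meandering scenario uses τ = 5 ms so its rotation cycle (~190 ms) puts
2–3 activations into each 500-sample analysis window. The dimensionless
`u` is recorded as Vm = −80 + 100·u mV, saturated to [−100, +40] mV
(only stimulated cells during the 2 ms pulses ever reach the cap).

Numerics: forward Euler, 5-point Laplacian, no-flux outer boundaries;
cells masked inexcitable exchange no diffusive flux (internal no-flux
obstacles). The explicit diffusion stability bound dt ≤ 0.9·dx²/(4D) is
enforced with a diagnostic error. Halving dt changes Vm by a bounded,
roughly first-order amount (asserted in the tests).

Scenarios (`rotormap.scenarios`) fix the study conditions: plane waves
are an S1 train at 300 ms cycle length from the left edge; rotors are
initiated by one S1 beat plus one cross-field S2 over the lower-left
5/8-square (coupling interval 330 ms for the anchored rotor, 180 ms for
the meandering one, values inside the vulnerable window found once and
frozen); the block line is the plane-wave scenario with a 0.75 × 8 mm
inexcitable strip. Initialization transients (one pacing cycle, or 1 s
for rotor formation) are cropped, so t = 0 of every recording is the
start of the analysis window. All scenarios are deterministic; the seed
only feeds optional S2 jitter and the recording noise below.

## Virtual electrograms

Each tissue cell contributes a current dipole ∝ ∇Vm; the unipolar EGM at
electrode position r′ (height h above the sheet) is

    Φe(r′) = −(σi/σe) (4π)^{-1} Σ_cells ∇Vm · ∇(1/|r′ − r|) dv,

with central-difference gradients, dv = dx²·(0.25 mm thickness, the 2D
reduction of the volume integral), σi/σe = 0.4, and a fixed global gain
calibrated once so a plane-wave unipolar deflection is ≈ 1 mV
peak-to-peak (the model itself carries no absolute amplitude scale; this
calibration makes the 0.01 mV ShEn bins meaningful). Electrode height
defaults to h = 1 mm, matching the 1 mm bipole spacing scale. Bipolar
EGMs subtract two unipolar recordings 1 mm apart.

Recordings add seeded white measurement noise of 0.005 mV RMS (~0.5% of
the plane-wave amplitude), a conservative clinical noise floor. This
matters scientifically: the rotor core is a low-voltage zone, so its
windows have a small standard deviation and hence a small absolute ApEn
tolerance; the fixed noise floor is therefore relatively larger exactly
where EGMs are fractionated, which reproduces the low-voltage/irregular
signature of real rotor-tip electrograms. A noiseless recording of this
deterministic model would be nearly periodic everywhere and grade far
more weakly.

Entropy maps are evaluated over an observation area that excludes 6 mm
next to a currently pacing edge (stimulus-artifact near-field; pacing
spikes are visible in the EGM up to a few mm away) and 3 mm along the
other borders (the artificial no-flux sheet boundary, absent in the
closed atrial surface, distorts wavefront termination there). Rotor
scenarios are recorded after all stimulation has ended, so only the
border margin applies to them.

## Entropy estimators

ApEn follows Pincus exactly: self-matches included, Chebyshev distance,
natural log, r = r_frac · SD of the analyzed window (each window of the
dynamic map is an independent evaluation). A constant window returns
exactly 0. The "standard parameters" mode is m = 2, r = 0.2·SD. The
vectorized implementation is checked against a literal O(N²) double-loop
oracle to 1e−12 on 200 seeded segments. `apen_profile` shares the
pairwise-distance work across the whole (m, r) grid (binning distances
into the tolerance ladder with one `searchsorted` pass), which is what
makes the 150-combination searches tractable; it is exact, not an
approximation.

ShEn is the Shannon entropy (bits) of the amplitude histogram with fixed
0.01 mV bins anchored at the window minimum, evaluated on 4 s windows.

## Fractionation classes and the synthetic database

The four expert classes are emulated with a derivative-of-Gaussian
biphasic deflection as the morphological primitive: C0 repeats one clean
deflection at a stable 150–250 ms cycle; C1 repeats one *fixed*
fractionated complex (3–5 sub-deflections over ~40 ms) — fractionated but
periodic; C2 alternates runs of 2–3 non-fractionated cycles with runs of
severe fractionated complexes (4–7 sub-deflections over ~80 ms) redrawn
every cycle — the regime switching and morphological instability are what
grade it above C1; C3 has exponentially distributed inter-deflection
intervals (mean 25 ms) with randomized amplitude and width and no
quiescent baseline. Signals are normalized to unit RMS before a 5% noise
floor is added, so classes differ in morphology rather than recording
gain, and activation times carry 2 ms jitter. With these defaults the
median ApEn(2, 0.2, 1000) grading is strictly C0 < C1 < C2 < C3 and the
Spearman correlation between ApEn(3, 0.38, 1000) and class index is
≈ 0.85–0.94 across seeds (the tests assert the ordering and ρ > 0.8).

What the generator does *not* emulate: catheter-contact and far-field
effects, inter-patient amplitude heterogeneity, class-imbalanced
composition, and real expert-labeling noise. Passing the grading tests
therefore shows the estimator and optimizer behave correctly on signals
with the defining morphological structure of each class, not that the
specific optimal (m, r) of any real database is recovered; that check
needs the real data (see the acceptance test that loads it).

## Parameter optimization

For each of the 150 grid combinations (m = 1..5, r = 0.02..0.60 step
0.02), ApEn of the first 500 or 1000 samples of every signal is min–max
normalized to [0, 1] across the dataset and split by class. Two criteria
are summed over the three adjacent class pairs: the interclass percentile
distance D_P = Σ [Q1(upper) − Q3(lower)] (type-7/linear-interpolation
quantiles — stated because D_P depends on the rule) and the interclass
min–max distance D_MM = Σ [min(upper) − max(lower)]. The objective
F = (D_P~ + D_MM~)/2 equally weights the two criteria after each is
min–max rescaled across the grid, since equal weighting is only
meaningful on a common scale. Ties in argmax F break toward smaller m,
then smaller r (prefer the simplest estimator). K-fold validation
(default K = 10, stratified, seeded) re-runs the search per training
fold and reports the agreement rate with the full-data optimum.

The parameter-recovery instrument (`generate_planted_dataset`) is a
symbolic, non-electrogram-shaped dataset whose optimum is pinned by
construction: a ternary coarse process with lag-m★ memory (iid below
embedding m★) plus an iid fine two-level component whose amplitude is
solved per signal to sit exactly at (r★ − 0.01)·SD, so tolerances below
r★ must match iid fine structure (separation collapses) and tolerances
from r★ up merge it (the class-graded coarse structure separates
cleanly, identically across the plateau, letting the tie-break select
exactly (m★, r★)). Grid search recovers the planted (3, 0.36) in 10/10
seeds and 10-fold validation agrees in every fold.

## LAT reference method and tip localization

Local activations are detected per electrode with a continuous wavelet
transform (derivative-of-Gaussian mother wavelet, 8 scales spanning
5–40 ms deflection widths), an amplitude-invariant robust threshold
min(median + 10·MAD, median + 0.7·(p99.5 − median)) on the summed
|coefficients| — the MAD arm suits quiet-baseline signals, the
peak-fraction cap handles periodic activity that inflates the MAD and
rejects secondary double-potential deflections near a core — followed by
50 ms blanking and refinement of each LAT to the steepest negative EGM
slope within ±10 ms. On the recovery fixtures this detects 5/5 planted
deflections within ±2 ms (clean) and ±5 ms (10 dB SNR) with no spurious
detections.

The rotor tip is the topological charge of the activation-phase field:
at each 100 ms scan reference, a site's phase is the time since its most
recent activation modulo the dominant cycle (the median over sites of
per-site median inter-activation intervals); staleness up to 2.5 cycles
is allowed because whole-cycle staleness is transparent under the
modulo. Charges are summed around 2 × 2 plaquettes, with perimeter rings
of radius 2–3 sites as fallback when a detection hole sits over the core,
tight +1/−1 pairs within 3 mm are discarded as phase-noise dipoles
(genuine counter-rotating cores sit a wavelength apart), and the tip is
the mean of the majority-charge singular sites over the interval's scans.
A plane wave yields no singular site ("no rotor", distinguished from an
error).

The ApEn-map tip is the amplitude-weighted centroid of the connected
component of sites at ≥ 90% of the frame maximum; no absolute "high
ApEn" threshold is ever hard-coded. A frame is declared rotor-free only
relative to a calibration floor, 1.2 × the global maximum of a
plane-wave (passive) calibration map.

## Benchmark results the code reproduces

Computed by `scripts/acceptance.py` and `tests/test_acceptance.py` at
full scale (128 × 128 sheet, dt = 0.05 ms, 33 × 33 electrodes at 1 mm,
1 kHz): the maximum windowed ApEn(3, 0.38, 1000) over all passive
plane-wave sites stays below 0.1; the LAT-method and ApEn-map tips of
the stable rotor agree within 1.66 mm in each of four 1 s intervals
(typically within ~0.7 mm); block-line sites grade strictly between
passive and rotor-tip levels; and the meandering-rotor map shows a hot
region in its observation box only while the wandering tip is inside it.
Windows in which the tip sits within ~1 mm of the box edge are genuinely
ambiguous and are not asserted either way.

## Known limitations

- The sheet is 2D, isotropic and homogeneous: no fiber orientation,
  anatomical structure, electrophysiological heterogeneity or fibrosis.
  Rates are flutter-like rather than fibrillatory; the "passive" regions
  are regularly paced, which is the easy end of the discrimination task.
- Tip localization is quantized by the 1 mm electrode pitch (plaquette
  centers are ±0.7 mm from any continuous position); sub-millimeter
  agreement figures are partly fortuitous cancellation.
- The entropy contrast at the core depends on the measurement-noise
  floor relative to the local signal amplitude (see the electrogram
  section); with an unrealistically clean recording chain the maps would
  lose sensitivity.
- The LAT detector's threshold is tuned for single-morphology periodic
  or moderately fractionated signals; continuously active C3-like
  signals with widely varying deflection amplitudes would need a lower
  peak-fraction cap.
- `load_db` auto-detects one-signal-per-file and matrix-per-class text
  layouts and assumes 1 kHz when no metadata says otherwise, flagging
  any disagreement at load time.
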