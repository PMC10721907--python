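# Methods

`retfield` couples a bioelectric volume-conductor model of an epiretinal
implant to multi-compartment retinal ganglion cell (RGC) cable models — a
"field-cable" approach: one linear field solve per electrode, reused for
every neuron and amplitude, followed by nonlinear membrane simulations to
locate activation thresholds.

## Virtual-patient geometry

Real inputs to such models are OCT-derived per-electrode measurements
(electrode–retina distance, retinal thickness, fibrotic tissue thickness).
Because patient imaging cannot be redistributed, the pipeline runs on
*virtual patients*: a 2.5-D height-field geometry — a regular lateral grid
carrying the inner-surface height, retinal thickness and fibrosis
thickness, with the electrode array on a tilted plane above the surface.
The layered representation matches the stacked anatomy (choroid, retina,
optional fibrosis, vitreous) and makes voxelization trivial; it cannot
represent folds or detachments, and electrode "visibility" is reduced to
lying inside the lateral grid.

Random fields are Gaussian-filtered white noise (length-scale 0.5 mm
default) scaled to a target standard deviation; degeneration and fibrosis
are circular patches. Defaults: 25 × 17 mm lateral domain, 18 mm of
vitreous above the array, 200 ± 20 µm retinal thickness, array tilt and
standoff configurable. Tilt produces the clinically observed spread of
electrode–retina distances across one array. Fibrosis hangs from the array
face, so an apposed electrode's distance equals its fibrosis thickness.
The generator is deterministic per seed, and the array plane is rejected
if it would intersect the retina within the array footprint.

The synthetic perceptual-threshold generator fills electrode tables with
`threshold = intercept + Σ coefficient·covariate + N(0, σ)` clipped at a
floor — the linear structure the statistical stage assumes — with default
slopes +500 µA/mm on distance and −300 µA/mm on thickness (thresholds rise
with lift-off and fall with remaining tissue). These tables exercise the
statistics; they are not used by the biophysical chain.

## Volume conductor

The quasi-static potential obeys ∇·(σ∇V) = 0. Conductivities (S/m):
vitreous 1.5, retina 0.100, fibrosis 0.15, choroid 0.503, platinum
9.43×10⁶, substrate 0 (perfect insulator). The retinal pigment epithelium
is a thin-layer contact conductance g = σ/t = 0.001/10 µm = 100 S/m²
applied to the faces on the retina–choroid interface rather than resolved
as voxels. The outer choroid face is the electrical ground (0 V); all
other outer boundaries are insulating.

Discretization is cell-centered finite-volume on an isotropic voxel grid
(default 25 µm; 50 µm — four voxels across an electrode, the coarsest
admitted — for batch studies). Face conductances are harmonic means of the
adjacent voxel conductivities; RPE faces add the contact conductance in
series. Each electrode's platinum voxels are collapsed into a single
equipotential super-node (Galerkin reduction of the assembled system),
which renders the active disc a true current terminal, inactive discs
exact floating potentials (zero net current), and removes the platinum
conductivity contrast from the linear system. The symmetric
positive-definite system is solved by Jacobi-preconditioned conjugate
gradients (relative residual 10⁻⁶ default); discrete current conservation
at the ground face holds to the solver residual.

The solver box (default 7.2 × 5.0 × 2.2 mm around the active electrode)
deliberately extends past the insulating substrate outline: if the box is
truncated at the substrate, all return current is forced through the local
RPE and the lateral potential profile under the array flattens — a
domain-truncation artifact. Box sizes beyond this default change predicted
thresholds by only a few percent.

Validation is against the analytic potential of an equipotential disc on
an insulating plane over a homogeneous half-space,
V(z) = I/(2πσa)·arctan(a/z). On a quarter-domain (the electrode center
placed on two insulating box faces, which are symmetry planes) at 25 µm
resolution the on-axis profile agrees within 5% beyond two voxels from
the face, the error decreases under grid refinement, and injected current
is conserved to < 0.5%.

## RGC populations and axon paths

Per electrode, 250 somata (default) are spread over a 700 µm-radius disc
by discrete Lloyd relaxation: a fixed dense uniform sample of the disc is
assigned to nearest seeds, and seeds move to their cell centroids;
50 iterations give near-hexagonal spacing. Somata sit 55 µm and axons
15 µm below the inner retinal surface; the hillock and sodium band ramp
between those depths. Neurons whose soma lies over retina thinner than
100 µm are removed (per-neuron by soma position, the finest reading of a
region-based rule); the per-electrode minimum threshold is re-aggregated
after removal without re-simulating.

Axon trajectories follow the Jansonius et al. (2009) nerve-fiber model:
in polar coordinates (r, φ) about the optic disc at (15°, 2°),
φ(r) = φ₀ + b(φ₀)(r−r₀)^c(φ₀) with r₀ = 4° and hemisphere-specific b, c
(superior: b = exp(−1.9 + 3.9·tanh(−(φ₀−121)/14)),
c = 1.9 + 1.4·tanh((φ₀−121)/14); inferior:
b = −exp(0.5 + 1.5·tanh(−(−φ₀−90)/25)), c = 1.0 + 0.5·tanh((−φ₀−90)/25)).
The inferior β = 0.5 is the corrected-coefficient variant used by common
phosphene-modelling software; every constant is overridable via
`TrajectoryParams`. Paths are confined to their launch hemisphere
(truncated before |φ| reaches 180°), somata exactly on the raphe are
assigned inferior, and inside r₀ the path continues as a straight radial
stub to the disc center. `soma_to_path` inverts the model by a bracketing
scan plus Brent root-find over φ₀. Conversion between retinal mm and
visual degrees uses the single factor 288 µm/degree; no
eccentricity-dependent magnification.

The dendritic tree is a single equivalent cylinder (200 µm × 2 µm,
extending opposite the axon at soma depth) — a deliberate stand-in for a
reconstructed arbor, adequate for extracellular threshold work where the
axon initial segment dominates. Axons are truncated at 1.2 mm arc length
by default: compartments farther away lie several length constants from
any field the electrode produces and do not move thresholds at the 0.1 µA
resolution.

## Membrane model and integration

Membrane dynamics are the five-conductance Fohlmeister–Miller-type
formulation: fast Na (m³h), Ca (c³), delayed-rectifier K (n⁴), A-type K
(a³h_A), Ca-activated K, and leak, with intracellular calcium driven by
I_Ca with 1.5 ms decay toward 0.1 µM and E_Ca from the Nernst relation.
All rate constants live in `membrane.py` (22 °C; a single Q10 = 2 factor
scales rates at other temperatures). Sectional channel densities (mS/cm²,
Na/Ca/K/A/KCa): dendrite 40/2/12/36/0.05, soma 80/1.5/18/54/0.065,
hillock 150/…, sodium band 700/… (the high-density spike-initiation
segment), axon 100/0/18/0/0; leak 0.05 everywhere, C_m = 1 µF/cm²,
R_axial = 110 Ω·cm, E_Na = +35 mV, E_K = −75 mV. The leak reversal is
solved per compartment at initialisation so the configured −65 mV rest is
an exact equilibrium — an unstimulated 200 ms run drifts < 1 µV. Near
threshold, spikes initiate in the sodium band/hillock, as expected for
epiretinal stimulation.

Extracellular stimulation enters through the axial terms of the cable
equation (intracellular potential = V_m + V_e), with V_e per compartment
equal to the unit-current field interpolated at the compartment center,
scaled by amplitude and the waveform — the linearity that makes one field
solve serve all amplitudes. Integration is semi-implicit at dt = 10 µs:
gates advance by exponential Euler at the current potential, then V_m is
solved implicitly along the chain (Thomas algorithm; numba-compiled).
Halving dt changes thresholds by ~1%. The integrator errors out on
non-finite or absurdly large (> 2×10⁴ mV) potentials; the transmembrane
potential is allowed to exceed physiological bounds *during* a strong
pulse because forced extracellular polarization at bracket-check
amplitudes legitimately does so without numerical instability.

Stimuli are charge-balanced cathodic-first biphasic pulses, 0.45 ms/phase
at 20 Hz (five pulses span 250 ms). Threshold search uses a single
biphasic pulse and a 6 ms simulated window by default — for this
deterministic model the first pulse determines threshold, and this cuts
runtime five-fold; the full train is available via configuration. A spike
is an upward crossing of 0 mV in any compartment. Bisection over
amplitude runs between 0 and 1000 µA to a 0.1 µA bracket (14 spike
evaluations plus the bracket check); if the upper bracket never spikes it
doubles up to 4× before the neuron is flagged inexcitable (NaN, excluded
from maps). Bisection assumes monotone activation; anodal upper
thresholds are outside scope.

## Phosphenes and statistics

Per electrode, the threshold map is the per-neuron thresholds plus the
minimum over retained neurons. "Activated at k× threshold" means a
neuron's own threshold ≤ k × the electrode minimum — valid under monotone
activation, and it makes the 1.2×–6× amplitude sweep free. Activated
somata are hulled (shapely convex hull); areas convert to deg² by
(288 µm/deg)⁻². The size–amplitude slope is the least-squares line of
hull area against the amplitude multiple over {1.2, 2, 3, 4, 5, 6}.

At the standard batch conditions (flat virtual patients at 50–300 µm
standoff, 100 neurons per electrode, 50 µm grid) minimum thresholds rise
from ~20 to ~260 µA and slopes from ~1.5 to ~3.3 deg²/×threshold, median
≈ 2.6–2.7. A known behaviour: at the largest standoffs the field is
laterally smooth enough that most of the 700 µm placement disc activates
by 3–4× threshold, so the area curve saturates and its linear-fit R²
falls to ~0.85–0.91 — an inherent consequence of the bounded placement
disc, insensitive to grid resolution and solver-box size.

The statistical stage mirrors the clinical analysis: electrodes enter if
visible and below the 677 µA cutoff (the device's operational
safe-charge-density cap; direct computation of 1.0 mC/cm²/phase on a
200 µm disc at 0.45 ms gives 698 µA — the 677 µA constant is kept as the
operational value and the discrepancy, possibly device amplitude
quantization, is noted here). Per-covariate OLS and a multiple regression
report R² and p-values (α = 0.05) through statsmodels behind
`ThresholdRegression` (a model object whose `.fit()` returns results with
`.summary()`); degenerate covariates (all-NaN fibrosis for patients
without growth, or spread below numerical noise) are dropped. Linear
mixed models with random intercept and slope are a thin delegation to
statsmodels `MixedLM`, not a re-implementation. On synthetic tables the
OLS recovers generator slopes within three standard errors, and permuted
responses reject at the nominal 5% rate.

## What the synthetic data do and do not show

The virtual patients reproduce the *structure* of the clinical inputs —
ranges of distance/thickness/fibrosis, their smoothness, and a linear
threshold dependence — but not real retinal anatomy, cystoid edema,
imaging artifacts, patient-specific RGC loss, or the psychophysics of
perception (criterion effects, cortical magnification). Passing tests
therefore demonstrate the correctness and calibration of the modelling
machinery, not clinical prediction accuracy for any real patient.
Patient-specific regression tables (which require private OCT data)
cannot be and are not reproduced.

## Problem sizes

Default production settings are 250 neurons/electrode at a 25 µm grid.
The test suite and acceptance script run scaled-down studies chosen as
representative desk-scale workloads: 50 µm grids for batch field solves,
a 25 µm quarter-domain for the oracle comparison, 100 neurons per
electrode, and 8-neuron single-electrode pipelines for orchestration
checks. All randomness is seeded; identical configurations reproduce
byte-identical outputs.
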