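# Methods

This note records the models specbind implements, the numerical choices
behind them, what the synthetic generators do and do not emulate, and the
known limitations. Units follow the conventions of the binding literature:
concentrations in mol/L inside the library (readers convert µmol/L at the
boundary), heats in µJ, molar enthalpies in kJ/mol, entropies in
J/(mol·K).

## Fluorescence quenching

The Stern-Volmer fit is ordinary least squares of F₀/F against [Q]. F₀ is
taken from the measured zero-quencher point of the same series, not refit.
The intercept is left free and reported: its ideal value is 1, and a
deviation flags curvature or a bad F₀ rather than being silently absorbed.
K_SV is the slope regardless; k_q = K_SV/τ₀ with τ₀ = 10⁻⁸ s, the
conventional unquenched biopolymer lifetime (overridable).

The double-logarithm fit regresses log₁₀((F₀−F)/F) on log₁₀[Q] using only
points with [Q] > 0 and F < F₀. Base-10 logarithms are used, the
convention under which log K_a values are quoted. Enhancement data is
refused rather than folded in with |F−F₀|: the model describes loss of
free fluorophore to a ground-state complex and has no defined meaning for
sensitization.

Mechanism classification is a fixed rule ladder — (1) all slopes negative
→ sensitization; (2) |k_q| above the 2.0 × 10¹⁰ L/mol/s
diffusion-collision ceiling → static; (3) otherwise K_SV rising with
temperature → dynamic, falling → static. A conflict between rules (2) and
(3) — k_q above the ceiling but K_SV rising — returns `ambiguous` with
every rule outcome recorded, never a silent tie-break. With one
temperature the trend rule is skipped and the evidence says so.

## Thermodynamics

The van't Hoff fit is linear in ln K_a vs 1/T, which assumes ΔH constant
over the temperature window; for the typical 288–308 K design this is the
standard approximation and a heat-capacity term would not be identifiable
from three points anyway. Force classification uses strict sign
inequalities on (ΔH, ΔS); exact zeros and the (+,−) quadrant — which the
classical rule set does not cover — map to `unclassified` rather than a
forced label.

A caution the package deliberately surfaces rather than hides: over a
20 K window the van't Hoff slope amplifies relative errors in K_a by
roughly ΔT⁻¹-scaled factors of 10³–10⁴ into ΔH. Titration noise of even
0.2% of F₀ produces several-kJ/mol scatter in ΔH and can flip the sign of
ΔS. The synthetic end-to-end bundle therefore uses 0.02% relative
titration noise so that a single run yields meaningful thermodynamics;
real studies should propagate K_a uncertainty before interpreting ΔS
signs.

## ITC

Integration: each injection's heat is the trapezoidal integral of
(power − baseline) from the injection time to the next injection, with the
baseline estimated as the median power over the preceding 20 s (window
configurable; it must not overlap the previous injection). µcal convert to
µJ at ×4.184. The molar-ratio axis is cumulative injected ligand moles
over initial cell protein moles — for the standard 20 × 2 µL of 600 µmol/L
into 300 µL of 30 µmol/L design this ends at 2.67.

The one-site model uses the perfusion-cell displaced-volume convention for
the post-injection concentrations,

    M_i = M₀(1 − ΔV_i/2V₀)/(1 + ΔV_i/2V₀),
    X_i = X_syr(ΔV_i/V₀)/(1 + ΔV_i/2V₀),

the physical root of the binding quadratic for the bound fraction Θ_i, and
per-injection heats q_i = Q_i − Q_{i−1} + (v_i/V₀)(Q_i + Q_{i−1})/2 +
q_dil. In the stoichiometric-binding limit this construction returns
exactly ΔH × (moles injected) for the first injection, which is the sanity
anchor used in the tests.

Fitting is bounded nonlinear least squares (lmfit/leastsq) over (n,
log₁₀K_a, ΔH, q_dil) with multistart across log₁₀K_a ∈ {3…7} and n ∈
{0.5, 1, 2}. The dilution offset can be fixed (`fit_dilution=False`),
appropriate after control subtraction; this matters quantitatively — at
c = nK_aM₀ ≈ 3 the Cramér-Rao bound on K_a roughly doubles when a free
offset is included. First-injection exclusion is available but off by
default. Near-constant heats (null signal or saturated-from-start design)
produce a warning and a flag on the result rather than a refusal. ΔH is
reported per mole of complex (the model parameter); the per-mole-of-
injectant normalization is available on the integrated heats.

## Amide-I secondary structure

Baseline correction subtracts the straight line through the absorbance at
1600 and 1700 cm⁻¹. Because real component bands have tails, the window
endpoints are not truly zero and endpoint anchoring leaves a small tilt;
the deconvolution model therefore includes a free linear baseline, which
removes an otherwise systematic ~1-point bias in the area fractions.

Components are pure Gaussians — mixed Gaussian-Lorentzian shapes add one
poorly identified parameter per band without materially changing area
fractions at 4 cm⁻¹ instrument resolution. Band seeding takes minima of
the Savitzky-Golay-smoothed second derivative with a ~10 cm⁻¹ physical
window (21 points at 0.5 cm⁻¹ spacing); narrower smoothing leaves noise
ripples that spawn spurious seeds. Minima shallower than 10% of the
deepest, and minima closer together than twice the minimum band width
(2 × 3 cm⁻¹ — two genuine bands cannot sit that close), are discarded or
merged. Shoulders buried too deep for the second derivative are recovered
by greedy growth: a band is proposed at the deepest unexplained
absorbance (plus a fresh equal-area-quantile start at the same count) and
kept only if the Bayesian information criterion improves, which stops
growth at the noise floor instead of shredding real bands into
noise-chasing fragments. Components under 0.5% of total area are pruned.
Centers are bounded to [1600, 1700] cm⁻¹ and sigmas to [3, 20] cm⁻¹.

Assignment bins are half-open — [1600, 1640) β-sheet, [1640, 1651) random
coil, [1651, 1661) α-helix, [1661, 1700] β-turn — resolving the
overlapping endpoint conventions (1639/1640, 1650/1651) quoted in the
literature deterministically. Fractions are normalized to sum to exactly
100. Ligand spectral contributions are assumed removed upstream (the
experimental dialysis step); this is an input requirement, not something
the code checks.

At 1% (of peak) noise the fraction estimates for heavily overlapped
coil/helix bands carry an information-theoretic floor of about 1 point of
standard deviation per class; the Monte-Carlo tests therefore check the
mean error over seeds, and single spectra should be read with that
uncertainty in mind.

## Stability kinetics

Percent remaining interpolates linearly in concentration between observed
time points (6 h sampling is too coarse to justify any curvature
assumption) and refuses to extrapolate. The first-order rate constant is
the slope of ln C vs t; endpoint percentages remain the primary,
model-free output, with k provided to make conditions comparable. The
protection effect reports the endpoint percentage-point difference
(with − without protein) and the rate ratio k_without/k_with, flagged
rather than reported as a number when the protected series is flat to
machine precision.

## Synthetic data

Generators produce: titrations from the static (F = F₀/(1+K_SV[Q])),
sensitization (F = F₀(1+|K_SV|[Q]), the linear mirror of the static form)
and n-site binding (F = F₀/(1+K_a[Q]ⁿ)) forward models; ITC thermograms as
Gaussian power pulses (FWHM 10 s — only areas matter downstream) whose
areas follow the same one-site model the fitter uses, at 200 s spacing on
a 1 s grid; amide-I spectra as Gaussian band mixtures with default centers
(1620, 1645, 1655, 1675) cm⁻¹ and widths σ = (7, 5, 5, 8) cm⁻¹ — FWHM
12–19 cm⁻¹, standard component widths, chosen so each band is resolvable
in the smoothed second derivative, the same property real band-fitting
protocols rely on; exponential degradation series (default: 17.5 µg/mL
sampled every 6 h to 36 h, k = 0.01494 h⁻¹ leaving 58.4% at the endpoint);
and EEM surfaces as 2-D Gaussians on a 5 nm × 2 nm grid.

All noise is additive Gaussian with user-set standard deviation — the
simplest defensible instrument model — and every generator is
bit-reproducible for a fixed seed. What the generators do *not* emulate:
inner-filter effects and detector nonlinearity in fluorescence, baseline
drift and injection-shape artifacts in ITC, water-vapor lines and
Fourier-self-deconvolution artifacts in FTIR, or LC peak-integration error
in the concentration tables. Passing tests on synthetic data therefore
demonstrate correct inversion of the stated forward models under Gaussian
noise, not robustness to every instrument pathology.

The end-to-end bundle ties the modalities together on one coherent truth:
binding with ΔH = −30 kJ/mol, ΔS = −18.33 J/(mol·K) (K_a(298 K) =
2 × 10⁴ L/mol, falling with temperature — static quenching, van der
Waals/H-bond signature), an ITC experiment with n = 1, K_a = 10⁵ L/mol,
ΔH = −20 kJ/mol plus a buffer control, a helix→sheet structural shift of
(−4.61, +3.80) points on complexation, and photodegradation that the
protein slows from 0.01494 h⁻¹ to 0.000817 h⁻¹ (58.4% vs ~97% remaining
at 36 h).

## Problem sizes and runtime

Monte-Carlo checks use 200 seeds for the linear fits (Stern-Volmer,
first-order rate), 100 for ITC and 50 for FTIR deconvolution — enough to
pin the mean/median error of each estimator to well under the tolerance
being asserted while keeping the full suite under a minute of fitting per
modality. The acceptance script runs one complete pipeline pass (~3 s).

## Known limitations

- No inner-filter correction; titration intensities are taken at face
  value.
- One binding model per modality: no multi-site/sequential ITC models, no
  cooperative quenching.
- Van't Hoff and ITC thermodynamics are reported side by side but never
  reconciled into a joint fit; they disagree in general (different
  observables, different assumptions), and the package takes no side.
- The FTIR pipeline estimates composition from band areas only; it does
  not attempt absolute secondary-structure accuracy against
  crystallographic benchmarks.
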