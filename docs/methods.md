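# Methods

## Reduced coordinates and the diabatic model

The chromophore is reduced to four internal coordinates: the bridge torsions
φ_P and φ_I (degrees in the public API, radians internally; zero angles are
the planar Z isomer, φ_I → 180° is Z→E isomerization), the bridge-carbon
pyramidalization θ (driven by methine hydrogen-out-of-plane motion; a single
angle stands in for the full internal-coordinate combination), and the
bond-length alternation r across the bridge (Å).

Three charge-localized diabatic states |P⟩, |I⟩, |B⟩ span the electronic
space. The diagonal entries are

    e_X(q) = e_X0 + t_XP·sin²φ_P + t_XI·sin²φ_I          (torsional modulation)
           + ½ k_bla (r − r_X)²                           (state-dependent BLA)
           + ½ k_θ θ²                                     (HOOP stiffness)
           − c_P sin²φ_I · θ²   (on |P⟩ only)             (HOOP gap closing)
           − c_I sin²φ_P · θ²   (on |I⟩ only)
           + U_scalar(q)

plus, on |I⟩ only, a Z/E well asymmetry ½·asym_I·(1 − cos φ_I) (the E isomer
sits slightly above Z). U_scalar is added equally to all three diagonals and
therefore changes no gap, coupling or degeneracy anywhere; it shapes the
landscape only:

* a conjugation ridge b_P sin²(2φ_P) + b_I sin²(2φ_I), zero at planar and
  twisted geometries, which sets the small mid-torsion S1 barriers (e.g. the
  ~0.05 eV I-torsion barrier of the in-plane methoxylated chromophore);
* a one-sided twist asymmetry ½·asym_twist·sin⁸φ_I·(√(cos²φ_I + ε²) −
  cos φ_I − ε), ε = 0.05, which vanishes on the whole Z side and at the
  planar, 90°-twisted and E geometries, and destabilizes the early E-side
  descent. It is the reduced-coordinate stand-in for the asymmetric
  I-ring-contraction relaxation of the real ground-state surface near the
  seam; without it a four-coordinate model is exactly mirror-symmetric about
  the 90° twist and every steepest-descent path from a +h displacement would
  end in the E well, for every chromophore. It is strong for HBDI⁻ and the
  methoxylated variants (1.8 eV) and weak for TFHBDI⁻ (0.15 eV), encoding the
  reduced ground-state inertial/relaxation asymmetry of the fluorinated
  chromophore.

Couplings are gated by the torsions (through-bridge superexchange):
v_PI = v_PI⁰ cos φ_P cos φ_I, v_PB = v_PB⁰ cos φ_P, v_IB = v_IB⁰ cos φ_I,
so every coupling involving a 90°-twisted fragment vanishes exactly (the
kernel snaps |cos| < 1e−14 to zero so the decoupling is exact in floating
point). v_PI⁰ is negative, which makes the in-phase P/I combination the
ground state; the bridge state then mixes into S0 and pushes the vertical
gap above the folded two-state value, as a bright-state treatment requires.

## Calibration

Free constants are fitted so that model observables reproduce the published
values for each chromophore:

| observable | HBDI⁻ | TFHBDI⁻ | MHBDI⁻ (in/out) |
|---|---|---|---|
| planar driving force Δ (eV) | −0.038 | −0.198 | −0.082 |
| planar folded coupling \|V\| (eV) | 1.092 | 1.112 | 1.065 |
| vertical-gap shift vs HBDI⁻ | — | blue, ≤ 0.05 eV | red |
| MECI-I pyramidalization | 12–40° (≈23°) | < 5° (≈0°) | — |
| E(MECI-P) − E(FC) | — | > 0.5 eV | — |
| \|E(MECI-I) − E(S1-I min)\| | — | < 0.1 eV | — |
| seam-MEP interior | ≈0.1 eV barrier | minimum | — |
| S1 I-torsion barrier | ≈0 | ≈0 | 0.05 ± 0.02 eV (in-plane) |
| twisted minima vs HBDI⁻ | — | — | within 0.05 eV (out-of-plane) |

The printed couplings are matched as the *bridge-folded effective* coupling
(Löwdin folding of |B⟩ at the mean P/I energy, evaluated at the relaxed
planar S0 minimum), not as the raw v_PI⁰; the printed numbers come from a
three-state analysis, so the folded convention is the faithful reading. The
two-parameter planar solve (Δ and |V|) is a fixed-point iteration; the
remaining constants are set by the general simplex calibrator
(`calibrate`), which minimizes weighted squared target violations with
multi-start Nelder–Mead. `validate_params` recomputes every observable from
scratch and reports pass/fail; all four shipped sets pass.

The energy zero of each parameter set is its relaxed planar S0 minimum
(stored as `e0`). The MECI-I pyramidalization is calibrated against the
level of theory used for the dynamics (≈30° for HBDI⁻, ≈0.4° for TFHBDI⁻ at
that level); the model lands at 23° / 0°, preserving the strong
HBDI-vs-TF contrast that controls seam access.

Inertial parameters are rigid-rotor moments Σ m_i d_i² about the bridge-bond
axis, computed from idealized (synthetic) ring geometries shipped as XYZ
fixtures: phenolate 89 amu·Å², trifluorophenolate 396, methoxyphenolate 201,
imidazolinone (with N/C-methyls) 259. The HOOP moment (1.3 amu·Å²,
essentially the methine hydrogen) and BLA reduced mass (6 amu) give
harmonic frequencies of ≈650 cm⁻¹ (HOOP) and ≈1170 cm⁻¹ (BLA) at the S0
minimum, in the range of the corresponding vibrations of the real
chromophore.

A uniform spectral shift of +0.379 eV aligns the model HBDI⁻ absorption
maximum (Wigner-sampled vertical gaps, oscillator-strength surrogate
∝ V²/gap, 0.07 eV FWHM convolution) with the 2.48 eV experimental band; the
same shift is applied to all chromophores when filtering initial conditions
by the pump window, mirroring how the reference protocol chose its +0.16 eV
shift for the ab initio gaps. The `absorption_spectrum` function keeps
+0.16 eV as its documentation default; the shipped parameter files carry
the model-calibrated value.

## Seam topology

At φ_I = 90° (φ_P = 0) the I-twisted fragment decouples and the S0/S1
crossing seam is the set of (θ, r) solving e_P = e_I, which exists for every
θ because the diagonal BLA difference is linear in r. For HBDI⁻ the seam
energy has two symmetric minima at θ ≈ ±23° separated by a ≈0.1 eV barrier;
these stand in for the two near-symmetry-related I-twisted intersections of
the full-dimensional chromophore (which differ in φ_I slightly above/below
90° — a distinction a cosine-gated model cannot make without breaking exact
decoupling). Trifluorination collapses the pair into a single seam minimum
at θ ≈ 0 that lies within 0.1 eV of the twisted S1 minimum: internal
conversion is no longer gated by pyramidalization. Branching planes are
built from the degenerate-subspace gradients, rotated to orthogonality; the
torsion-dominated direction is labeled h (sign convention: +h toward
increasing φ_I, i.e. the E isomer) and the BLA/HOOP direction g.

## Dynamics surrogate

The reference nonadiabatic dynamics for this problem is ab initio multiple
spawning; this package uses fewest-switches surface hopping (FSSH) as a
desk-scale surrogate, so population traces and yields are meaningful as
orderings and fractions, not as quantitative reproductions of wavepacket
results. Specifics:

* Initial conditions: thermal Wigner distribution of the four harmonic
  modes at the planar S0 minimum, 300 K; each sample carries its vertical
  gap and is promoted to S1. Samples are filtered by the pump window
  (2.48 ± 0.05 eV on shifted gaps) and re-weighted.
* Integration: velocity Verlet, base step 0.25 fs, halved whenever the
  largest |d·v| exceeds 0.005 a.u.-equivalent (0.207 fs⁻¹) — the analogue of
  the reference protocol's adaptive step in coupling regions. Electronic
  amplitudes are propagated by RK4 in the adiabatic basis with phase-aligned
  eigenvectors.
* Hopping: standard fewest-switches probabilities from the amplitude flux;
  momentum rescaled along the derivative-coupling direction at hops;
  frustrated hops reverse the momentum component along d.
* Decoherence: energy-based damping of inactive amplitudes with constant
  C = 0.1 hartree (2.72 eV) and the kinetic-energy prefactor.
* Termination: 10 ps default horizon (3 ps in the shipped comparison
  protocols — by then the TF ensemble is fully decayed and the HBDI ensemble
  fit is stable); after relaxing to S0 a trajectory continues for 150 fs and
  is then classified from its final φ_I: Z within ±55°, E within ±55° of
  180°, otherwise unassigned; trajectories that never reach S0 are
  "trapped". The AIMS spawning threshold and minimum-population rules map to
  the step-halving trigger and the S0-continuation stop.
* Seeds: per-trajectory integer seeds drawn from one master generator; all
  outputs record them, and identical (IC, seed) pairs reproduce bitwise.
* Energy conservation between hops is tracked; drift beyond 0.01 eV flags
  the trajectory invalid and excludes it (with a warning) from ensembles.
  Typical drift at the default step is below 10⁻³ eV.

"Initial P-twisting" is operationalized as the first bridge torsion to pass
45°; the published analysis states no threshold.

## Analytics

* S1 population traces are weighted active-state fractions on a uniform
  grid; the delayed biexponential P(t) = 1 for t ≤ t0, a·e^(−(t−t0)/τ1) +
  (1−a)·e^(−(t−t0)/τ2) after, is fitted by trust-region least squares with
  10 multi-starts on t0 ∈ [0, 500] fs (ties: lowest residual, then lowest
  t0); a sharp onset is used since the published functional form does not
  specify smoothing. Fits with a → 0/1 or τ2/τ1 < 1.25 carry a degenerate
  flag. Errors come from bootstrap over initial conditions (default 1500
  cycles; degenerate refits dropped and counted) or, for single traces,
  residual resampling.
* Reduced densities along a torsion are Monte-Carlo sums of 8° Gaussian
  kernels at trajectory angles, weighted by trajectory weight and S1
  occupancy, so each time slice integrates to the instantaneous S1
  population. The kernel width is a display choice; halving it sharpens
  ridges without moving them.
* Committor analysis samples the branching plane on polar grids (default
  radii 0.05/0.1/0.2 in internal units — radians for torsional
  displacement — and 24 angles) and runs 300 fs of ground-state dynamics per
  sample in three limits: steepest descent in mass-weighted coordinates
  (all kinetic energy quenched continuously), a single trajectory from
  rest, and 50 trajectories with isotropic random velocities whose total
  kinetic energy is the 300 K equipartition value over the four modes.
  Unassigned endpoints are excluded from the p_E denominator and reported.
  The equicommittor is the bilinear 0.5 level set of the random-velocity
  map. Hop-velocity distributions project hop-frame velocities onto +h and
  fold the two twist directions together by flipping the sign on the
  negative-φ_I side.

## What the synthetic generator does and does not emulate

`synth_trace` and `synth_ensemble` produce population traces and labeled
trajectory collections with exactly known ground truth (delayed
biexponential decays, prescribed hop-time distributions and photoproduct
probabilities) for testing the fitting, bootstrap, density and yield
analytics independently of the dynamics. They emulate the *structure* of
surface-hopping output, not its physics: no geometry evolution beyond the
final label, no energy conservation, no correlations between hop time and
outcome. Passing those tests therefore validates the analytics chain, while
the calibrated-surface tests validate the physics qualitatively; neither
implies quantitative agreement with wavepacket dynamics on ab initio
surfaces, whose headline numbers (58% vs ~30% yield, 361 fs vs 909 fs) the
surrogate is only required to order, not match.

## Numerical choices

* Eigenvectors: deterministic phase (largest-magnitude component positive,
  ties to the lowest index); along trajectories, signs follow continuity
  with the previous step.
* MECI searches: smooth penalty mean(E) + σ·gap²/(gap + α), α = 0.02 eV,
  σ doubled from 3.5 until the gap is below 10⁻⁴ eV; L-BFGS-B with analytic
  penalty gradients; coordinate bounds θ ∈ [−90°, 90°], r ∈ [−0.3, 0.3] Å.
* NEB: FIRE-optimized band with improved (upwind) tangents and spring
  constant 1.0 in mass-weighted coordinates built from the diagonal
  inertia tensor (no kinetic coupling between reduced coordinates); the
  barrier is max(E) − E(start). Seam MEPs run the same band on the
  penalized mean-energy surface with σ = 600 and report mean S0/S1
  energies; every converged image stays within 10⁻³ eV of degeneracy.
* Steepest-descent (MEP) committor: fixed mass-weighted arc steps of 0.05
  (√eV·fs units), converged below a 10⁻⁵ projected-gradient norm; outcomes
  are step-size independent well above this.
* Degenerate inputs: derivative couplings refuse gaps below 10⁻⁸ eV;
  two-state folding refuses a bridge state at or below the P/I block;
  Wigner sampling refuses non-positive Hessian eigenvalues.

## Known limitations

* Four reduced coordinates with a diagonal inertia tensor: no kinetic
  coupling, no explicit I-ring skeletal relaxation (its ground-state effect
  enters only through the scalar twist asymmetry), no solvent or protein.
* FSSH with independent trajectories cannot reproduce wavepacket
  coherences; the long-lived (~10 ps) trapped component is represented but
  its timescale is not calibrated.
* The intersection-pair topology lives in the pyramidalization coordinate
  rather than slightly off-90° torsions (see "Seam topology").
* The absorption oscillator-strength surrogate (V²/gap) is adequate for
  window filtering and peak location only.
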