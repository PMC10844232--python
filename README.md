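# chromodyn

Reduced-coordinate models and surrogate nonadiabatic dynamics for the
excited-state decay of the anionic GFP chromophore (HBDI⁻) and its P-ring
substituted derivatives — the 2,3,5-trifluorinated (TFHBDI⁻) and
3-methoxylated (MHBDI⁻) analogues.

Photoexcited HBDI⁻ decays by twisting about either of the two methine-bridge
bonds: rotation about the imidazolinone-side bond (the I-torsion, φ_I) can
complete Z→E photoisomerization, while rotation about the phenolate-side
bond (the P-torsion, φ_P) only regenerates the Z isomer. Which channel wins,
how fast the molecule reaches the S1/S0 intersection seam, and what fraction
of the population ends as the E photoproduct are all controlled by the
substituents on the phenolate ring. `chromodyn` packages this physics as a
calibrated, testable pipeline for method development and teaching: model
surfaces with analytic gradients, trajectory surface hopping, decay-constant
fitting, and committor analysis around conical intersections.

## The model

The electronic structure near the bridge is a three-state diabatic
Hamiltonian over charge-localized states |P⟩, |I⟩, |B⟩ (excess charge on the
phenolate ring, the imidazolinone ring, or the bridge):

    H(q) = [ e_P(q)   v_PI(q)  v_PB(q) ]
           [ v_PI(q)  e_I(q)   v_IB(q) ]
           [ v_PB(q)  v_IB(q)  e_B(q)  ]

over four reduced coordinates q = (φ_P, φ_I, θ_HOOP, BLA): the two bridge
torsions, the bridge-carbon pyramidalization (methine hydrogen-out-of-plane
angle) and the bond-length alternation. Couplings are gated by the torsions
— every coupling involving |P⟩ carries cos φ_P and every coupling involving
|I⟩ carries cos φ_I — so a 90° twist decouples the rotated fragment exactly.
Diagonalizing H gives the adiabatic states S0, S1, S2; Löwdin-folding |B⟩
out of the planar matrix gives the effective two-state picture in which the
S1–S0 gap is √(Δ² + 4V²), with Δ = e_P − e_I the diabatic driving force and
V the effective P/I coupling.

The shipped parameter sets are calibrated to the published diabatic analysis
and stationary-point energetics of the three chromophores
(Δ = −0.038 / −0.198 / −0.082 eV and V = 1.092 / 1.112 / 1.065 eV for
HBDI⁻ / TFHBDI⁻ / MHBDI⁻; intersection energetics and pyramidalization;
excited-state torsional barriers). Fragment moments of inertia come from
rigid-rotor sums over idealized ring geometries, so the heavier fluorinated
and methoxylated rings genuinely twist more slowly. Excited-state dynamics
uses fewest-switches surface hopping with an energy-based decoherence
correction: thermal Wigner sampling at 300 K, pump-window filtering,
velocity-Verlet propagation with analytic Hellmann–Feynman gradients and
derivative couplings, momentum rescaling at hops, and photoproduct
classification from the final I-torsion (±55° windows). See
`docs/methods.md` for the full model definition and its limitations.

## Worked example

Run a 100-trajectory surface-hopping ensemble on the trifluorinated
chromophore and fit its S1 decay:

```
$ chromodyn dynamics --chromophore TFHBDI --n-traj 100 --seed 7 --out demo_tf
{
  "quantum_yield_E": 0.76,
  "fraction_trapped": 0.05,
  "fraction_initial_P_twist": 0.0,
  "n_trajectories": 100,
  "seed": 7,
  "chromophore": "TFHBDI"
}
$ chromodyn analyze demo_tf/population.csv
{
  "t0_fs": 412.4,
  "tau1_fs": 154.3,
  "tau2_fs": 824.4,
  "amplitude_a": 0.213,
  ...
}
```

Reading the output: 76% of the excited population isomerizes to the E
photoproduct, none of it twists the unproductive P-bond first, and the S1
population follows a delayed biexponential — a lag while the wavepacket
leaves the Franck–Condon region, then a fast internal-conversion component
(τ1) through the I-twisted intersection seam and a slower residual (τ2).
Running the same protocol on unsubstituted `HBDI` gives a markedly lower E
yield and slower decay, and a large initial-P-twist fraction: the
substituent effect the package is built to dissect.

The same workflow is available as a library:

```python
from chromodyn import (builtin_params, sample_wigner,
                       filter_excitation_window, run_ensemble)

params = builtin_params("TFHBDI")
ics = sample_wigner(params, 1000, temperature_K=300.0, seed=1)
ics = filter_excitation_window(ics, 2.48, 0.05,
                               shift_eV=params.spectral_shift)
ensemble = run_ensemble(params, ics, seed=1)
print(ensemble.summary())
```

Committor maps around the I-twisted intersections (`chromodyn committor`),
parameter validation against the calibration targets (`chromodyn validate`)
and re-calibration of user-modified parameter sets (`chromodyn calibrate`)
round out the CLI.

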