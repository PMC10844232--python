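"""Three-state diabatic Hamiltonian of the anionic GFP chromophore.

The electronic structure near the methine bridge is described by three
charge-localized diabatic states: |P> (excess charge on the phenolate ring),
|I> (imidazolinone ring) and |B> (bridge).  Diagonalizing the 3×3 diabatic
matrix at a reduced geometry gives the adiabatic states S0, S1, S2.
Twisting a bridge bond decouples the rotated fragment: every coupling
involving |P> carries a factor cos(phi_P) and every coupling involving |I>
a factor cos(phi_I), so couplings vanish exactly at 90° twists.

The P/I driving force Delta = e_P - e_I and the bridge-folded effective
coupling V_eff control the planar S1-S0 gap via sqrt(Delta² + 4 V_eff²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import ReducedGeometry
from .params import ChromophoreParams

__all__ = [
    "DiabaticMatrix",
    "AdiabaticSolution",
    "build_hamiltonian",
    "adiabatize",
    "effective_two_state",
    "diabatic_characters",
]

LABELS = ("P", "I", "B")


@dataclass(frozen=True)
class DiabaticMatrix:
    """Symmetric 3×3 diabatic matrix in the (|P>, |I>, |B>) basis, eV."""

    e_P: float
    e_I: float
    e_B: float
    v_PI: float
    v_PB: float
    v_IB: float

    def __post_init__(self):
        for f in ("e_P", "e_I", "e_B", "v_PI", "v_PB", "v_IB"):
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"non-finite matrix element {f}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                [self.e_P, self.v_PI, self.v_PB],
                [self.v_PI, self.e_I, self.v_IB],
                [self.v_PB, self.v_IB, self.e_B],
            ]
        )

    @property
    def driving_force(self) -> float:
        """Diabatic P/I driving force Delta = e_P - e_I, eV."""
        return self.e_P - self.e_I


@dataclass(frozen=True)
class AdiabaticSolution:
    """Eigen-decomposition of a diabatic matrix.

    ``energies`` are sorted ascending (S0, S1, S2); ``eigenvectors`` holds
    the states in columns with the phase convention that the largest-
    magnitude component is positive; ``characters`` are the squared weights
    of each adiabatic state on the diabatic basis.
    """

    energies: np.ndarray
    eigenvectors: np.ndarray
    characters: np.ndarray

    @property
    def gap(self) -> float:
        """S1 - S0 energy gap, eV."""
        return float(self.energies[1] - self.energies[0])

    def dominant_label(self, state: int) -> str:
        return LABELS[int(np.argmax(self.characters[state]))]


def build_hamiltonian(params: ChromophoreParams, q: ReducedGeometry) -> DiabaticMatrix:
    """Evaluate the diabatic matrix of ``params`` at geometry ``q``.

    Diagonal entries include the torsional modulations, the HOOP
    (pyramidalization) gap-closing terms and the harmonic BLA terms;
    off-diagonal couplings are gated by the cosines of the bridge torsions.
    """
    params.validate()
    p = params.to_array()
    qa = q.to_array()
    n, nc = 3, 4
    H = np.zeros((n, n))
    dH = np.zeros((nc, n, n))
    _kernels.eval_model(_kernels.MODEL_CHROMO, p, qa, H, dH)
    return DiabaticMatrix(
        e_P=H[0, 0], e_I=H[1, 1], e_B=H[2, 2],
        v_PI=H[0, 1], v_PB=H[0, 2], v_IB=H[1, 2],
    )


def adiabatize(H: DiabaticMatrix | np.ndarray) -> AdiabaticSolution:
    """Diagonalize a diabatic matrix into the adiabatic states."""
    A = H.to_array() if isinstance(H, DiabaticMatrix) else np.asarray(H, float)
    if A.shape != (3, 3) or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("diabatic matrix must be symmetric 3x3")
    if not np.all(np.isfinite(A)):
        raise ValueError("diabatic matrix must be finite")
    E, U = np.linalg.eigh(A)
    _kernels.fix_phases(U)
    return AdiabaticSolution(energies=E, eigenvectors=U, characters=(U.T**2))


def effective_two_state(H: DiabaticMatrix) -> tuple[float, float, float]:
    """Löwdin-fold |B> out of the 3×3 matrix at the mean P/I energy.

    Returns ``(delta, v_eff, gap)``: the effective two-state driving force,
    the bridge-folded effective P/I coupling, and the two-state gap
    ``sqrt(delta² + 4 v_eff²)`` — the quantity the printed planar driving
    forces and couplings parametrize.

    Requires e_B strictly above the P/I block.
    """
    if H.e_B <= max(H.e_P, H.e_I) + 1e-9:
        raise ValueError("degenerate partitioning: e_B not above the P/I block")
    e0 = 0.5 * (H.e_P + H.e_I)
    denom = e0 - H.e_B
    eP = H.e_P + H.v_PB**2 / denom
    eI = H.e_I + H.v_IB**2 / denom
    v = H.v_PI + H.v_PB * H.v_IB / denom
    delta = eP - eI
    gap = float(np.sqrt(delta**2 + 4.0 * v**2))
    return float(delta), float(v), gap


def diabatic_characters(sol: AdiabaticSolution) -> dict:
    """Per-state squared diabatic weights and dominant-label tags."""
    out = {}
    for s, name in enumerate(("S0", "S1", "S2")):
        w = sol.characters[s]
        out[name] = {
            "weights": {lab: float(w[i]) for i, lab in enumerate(LABELS)},
            "dominant": sol.dominant_label(s),
        }
    return out
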