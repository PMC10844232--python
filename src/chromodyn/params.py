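"""Chromophore parameter sets for the three-state diabatic model.

A :class:`ChromophoreParams` instance fully specifies one chromophore's
diabatic surfaces over the reduced coordinates (phi_P, phi_I, theta_hoop,
bla), the coupling amplitudes and their torsional gating, and the inertial
parameters of the four reduced modes.  Parameter files are TOML with a
versioned ``format = 1`` key; see :func:`load_params` / :func:`save_params`.

Energies are in eV, HOOP constants in eV/rad², BLA constants in eV/Å²,
torsional inertia in amu·Å², the HOOP reduced moment in amu·Å² and the BLA
reduced mass in amu.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ChromophoreParams", "load_params", "save_params", "PARAM_FIELDS"]

# Field order of the packed parameter vector consumed by the numba kernels.
PARAM_FIELDS = (
    "e_P0", "e_I0", "e_B0",
    "t_PP", "t_PI", "t_IP", "t_II", "t_BP", "t_BI",
    "asym_I",
    "c_P", "c_I",
    "k_theta", "k_bla",
    "r_P", "r_I", "r_B",
    "v_PI0", "v_PB0", "v_IB0",
    "b_P", "b_I",
    "inertia_P", "inertia_I", "mass_theta", "mass_bla",
    "e0",
    "asym_twist",
)


@dataclass
class ChromophoreParams:
    """Full parametrization of one chromophore's diabatic model.

    Diagonal diabatic energies (|P>, |I>, |B>) are built from planar values
    ``e_X0``, torsional modulations ``t_XY`` (state X along torsion Y,
    multiplying sin²(phi_Y)), a Z/E asymmetry ``asym_I`` on |I> along phi_I,
    HOOP gap-closing constants ``c_P``/``c_I``, a common HOOP stiffness
    ``k_theta``, harmonic BLA terms with state-dependent minima ``r_X``, and
    a state-independent conjugation ridge ``b_P/b_I`` (multiplying
    sin²(2·phi)).  Couplings are gated by the bridge torsions:
    ``v_PI = v_PI0·cos(phi_P)·cos(phi_I)``, ``v_PB = v_PB0·cos(phi_P)``,
    ``v_IB = v_IB0·cos(phi_I)``.
    """

    name: str = "custom"

    # planar diagonal energies, eV
    e_P0: float = 0.0
    e_I0: float = 0.0
    e_B0: float = 2.5

    # torsional diagonal modulation amplitudes, eV (state, torsion)
    t_PP: float = 0.0
    t_PI: float = 0.0
    t_IP: float = 0.0
    t_II: float = 0.0
    t_BP: float = 0.4
    t_BI: float = 0.4

    # Z/E asymmetry of |I> along phi_I, eV (multiplies (1-cos phi_I)/2)
    asym_I: float = 0.0

    # twisted-region Z-restoring asymmetry of |I>, eV: -asym_twist·sin²(phi_I)·
    # cos(phi_I) — the ground-state analogue of the asymmetric I-ring
    # relaxation near the seam; vanishes at planar, twisted and E geometries
    asym_twist: float = 0.0

    # HOOP gap-closing constants, eV/rad²
    c_P: float = 0.9
    c_I: float = 0.9

    # HOOP stiffness (eV/rad²) and BLA force constant (eV/Å²)
    k_theta: float = 2.0
    k_bla: float = 30.0

    # state-dependent BLA minima, Å
    r_P: float = -0.025
    r_I: float = 0.025
    r_B: float = 0.0

    # coupling amplitudes, eV
    v_PI0: float = 1.2
    v_PB0: float = 0.51
    v_IB0: float = 0.51

    # conjugation ridge along each torsion, eV (multiplies sin²(2 phi))
    b_P: float = 0.05
    b_I: float = 0.05

    # inertial parameters
    inertia_P: float = 90.0    # amu·Å²
    inertia_I: float = 160.0   # amu·Å²
    mass_theta: float = 1.3    # amu·Å²
    mass_bla: float = 6.0      # amu

    # energy origin: raw adiabatic S0 energy at the planar minimum, eV
    e0: float = 0.0

    # uniform spectral shift aligning the computed absorption maximum with
    # the experimental band (applied when comparing to pump windows), eV
    spectral_shift: float = 0.16

    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for f in PARAM_FIELDS:
            v = getattr(self, f)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {f}={v!r}")
        for f in ("k_theta", "k_bla", "inertia_P", "inertia_I",
                  "mass_theta", "mass_bla"):
            if getattr(self, f) <= 0:
                raise ValueError(f"parameter {f} must be strictly positive")

    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 vector used by the numba kernels."""
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, vec: np.ndarray, name: str = "custom") -> "ChromophoreParams":
        kw = {f: float(v) for f, v in zip(PARAM_FIELDS, vec)}
        return cls(name=name, **kw)

    @property
    def masses(self) -> np.ndarray:
        """Diagonal mass/inertia tensor over (phi_P, phi_I, theta, bla)."""
        return np.array(
            [self.inertia_P, self.inertia_I, self.mass_theta, self.mass_bla]
        )

    def replace(self, **kw) -> "ChromophoreParams":
        return dataclasses.replace(self, **kw)


def load_params(path: str | Path) -> ChromophoreParams:
    """Read a chromophore parameter file (TOML, ``format = 1``)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    fmt = doc.get("format")
    if fmt != 1:
        raise ValueError(f"unsupported parameter file format: {fmt!r}")
    kw: dict = {"name": doc.get("name", Path(path).stem)}
    for table in ("diabatic", "inertia", "reference"):
        for k, v in doc.get(table, {}).items():
            if k in PARAM_FIELDS or k == "spectral_shift":
                kw[k] = float(v)
    return ChromophoreParams(**kw)


_TABLES = {
    "diabatic": PARAM_FIELDS[:22] + ("asym_twist",),
    "inertia": PARAM_FIELDS[22:26],
    "reference": ("e0", "spectral_shift"),
}


def save_params(params: ChromophoreParams, path: str | Path) -> None:
    """Write a chromophore parameter file (TOML, ``format = 1``)."""
    lines = [f'name = "{params.name}"', "format = 1", ""]
    for table, fields in _TABLES.items():
        lines.append(f"[{table}]")
        for f in fields:
            lines.append(f"{f} = {float(getattr(params, f))!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
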