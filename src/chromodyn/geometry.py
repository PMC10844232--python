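"""Reduced internal coordinates of the methine-bridge chromophore.

The four coordinates are the two bridge torsions (phenolate ``phi_P`` and
imidazolinone ``phi_I``), the bridge-carbon pyramidalization / methine
hydrogen-out-of-plane angle ``theta_hoop``, and the bond-length alternation
``bla`` across the bridge.  Zero torsions correspond to the planar Z isomer;
``phi_I`` -> 180° is the Z->E isomerization coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReducedGeometry", "wrap_angle_deg"]


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    a = float(np.remainder(angle, 360.0))
    if a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class ReducedGeometry:
    """A point in reduced coordinate space.

    Parameters
    ----------
    phi_P, phi_I : float
        Bridge torsions in degrees, wrapped to (-180, 180].
    theta_hoop : float
        Bridge pyramidalization angle in degrees.
    bla : float
        Bond-length alternation in Å.
    """

    phi_P: float = 0.0
    phi_I: float = 0.0
    theta_hoop: float = 0.0
    bla: float = 0.0

    def __post_init__(self):
        for name in ("phi_P", "phi_I", "theta_hoop", "bla"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite coordinate {name}={v!r}")
        object.__setattr__(self, "phi_P", wrap_angle_deg(self.phi_P))
        object.__setattr__(self, "phi_I", wrap_angle_deg(self.phi_I))
        object.__setattr__(self, "theta_hoop", wrap_angle_deg(self.theta_hoop))

    def to_array(self) -> np.ndarray:
        """Internal representation: [phi_P, phi_I, theta_hoop] in rad, bla in Å."""
        return np.array(
            [
                np.deg2rad(self.phi_P),
                np.deg2rad(self.phi_I),
                np.deg2rad(self.theta_hoop),
                self.bla,
            ]
        )

    @classmethod
    def from_array(cls, q: np.ndarray) -> "ReducedGeometry":
        q = np.asarray(q, dtype=float)
        return cls(
            phi_P=np.rad2deg(q[0]),
            phi_I=np.rad2deg(q[1]),
            theta_hoop=np.rad2deg(q[2]),
            bla=float(q[3]),
        )
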