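"""Allometric body-mass estimation and great-circle distance.

Body mass of a bearded seal is predicted from standard length L (cm) and
girth G (cm) by the allometric power law

    B = exp(a) * L^p * G^q        [kg]

with a = -8.7167, p = 1.0135, q = 1.7686.  Girth carries most of the
signal (q close to 2, as for a cylinder of fixed density); length enters
nearly linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = ["MassEquationParams", "estimate_body_mass", "great_circle_distance"]


@dataclass(frozen=True)
class MassEquationParams:
    intercept_log: float = -8.7167
    length_exponent: float = 1.0135
    girth_exponent: float = 1.7686

    def __post_init__(self):
        if self.length_exponent <= 0 or self.girth_exponent <= 0:
            raise ValueError("allometric exponents must be positive")


def estimate_body_mass(length_cm, girth_cm,
                       params: MassEquationParams = MassEquationParams()):
    """Predicted body mass (kg) from standard length and girth (cm)."""
    L = np.asarray(length_cm, float)
    G = np.asarray(girth_cm, float)
    if np.any(L <= 0) or np.any(G <= 0):
        raise ValueError("length and girth must be positive")
    mass = np.exp(params.intercept_log) * L ** params.length_exponent \
        * G ** params.girth_exponent
    return float(mass) if mass.ndim == 0 else mass


def great_circle_distance(lat1, lon1, lat2, lon2, radius_km: float = 6371.0):
    """Haversine great-circle distance in km on a spherical Earth."""
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))
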