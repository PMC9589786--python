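"""Distortion energies and the 16-feature shape signature.

A local distortion is a function E(sigma1, sigma2) of the Jacobian singular
values of the flattening on one triangle.  Eight closed-form energies are
used, covering the four classical families:

    isometric   ARAP(s1,s2) = (s1^2-1)^2 + (s2^2-1)^2
                SD(s1,s2)   = (s1^2 + s1^-2 + s2^2 + s2^-2) / 4
                QI(s1,s2)   = max(s1, 1/s2)
    conformal   QC(s1,s2)   = max(s1/s2, s2/s1)
                MIPS(s1,s2) = s1/s2 + s2/s1
    area        AD(s1,s2)   = max(|s1 s2|, 1/|s1 s2|)
    scale       Dirichlet   = (s1^2 + s2^2) / 2
                CF          = (s1 + s2) / 2

All are rotation invariant (functions of singular values only).  The global
distortion of a map over a triangle subset is the area-weighted mean of the
local values, with areas taken from the source 3D mesh.  Triangles are split
into a low- and a high-frequency band at the median centroid frequency, and
the 8 energies x 2 bands give the 16-dimensional signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .flattening import FlattenConfig, PlanarEmbedding, flatten
from .meshing import TriMesh

__all__ = [
    "ENERGY_NAMES",
    "FEATURE_NAMES",
    "EnergyRegistry",
    "evaluate_energy",
    "FrequencySplit",
    "split_by_frequency",
    "global_distortion",
    "DistortionSignature",
    "extract_signature",
]

logger = logging.getLogger(__name__)


def _arap(s1, s2):
    return (s1**2 - 1.0) ** 2 + (s2**2 - 1.0) ** 2


def _symmetric_dirichlet(s1, s2):
    return 0.25 * (s1**2 + s1**-2 + s2**2 + s2**-2)


def _quasi_isometric(s1, s2):
    return np.maximum(s1, 1.0 / s2)


def _quasi_conformal(s1, s2):
    return np.maximum(s1 / s2, s2 / s1)


def _mips(s1, s2):
    return s1 / s2 + s2 / s1


def _area_distortion(s1, s2):
    prod = np.abs(s1 * s2)
    return np.maximum(prod, 1.0 / prod)


def _dirichlet(s1, s2):
    return 0.5 * (s1**2 + s2**2)


def _conformal_factor(s1, s2):
    return 0.5 * (s1 + s2)


#: Canonical energy order (fixed; feature vectors follow it energy-major).
ENERGY_NAMES = ("ARAP", "SD", "QI", "QC", "MIPS", "AD", "Dirichlet", "CF")

EnergyRegistry = {
    "ARAP": _arap,
    "SD": _symmetric_dirichlet,
    "QI": _quasi_isometric,
    "QC": _quasi_conformal,
    "MIPS": _mips,
    "AD": _area_distortion,
    "Dirichlet": _dirichlet,
    "CF": _conformal_factor,
}

#: Lower bound of each energy over sigma1 >= sigma2 > 0.
ENERGY_LOWER_BOUNDS = {
    "ARAP": 0.0,
    "SD": 1.0,
    "QI": 1.0,
    "QC": 1.0,
    "MIPS": 2.0,
    "AD": 1.0,
    "Dirichlet": 0.0,
    "CF": 0.0,
}

#: Signature feature names: energy-major, band-minor.
FEATURE_NAMES = tuple(f"E_{name}_{band}" for name in ENERGY_NAMES for band in (1, 2))


def evaluate_energy(name: str, sigma1, sigma2):
    """Closed-form value of the named distortion energy.

    Requires positive singular values (an inverted or collapsed triangle has
    no finite distortion).  Accepts scalars or arrays.
    """
    if name not in EnergyRegistry:
        raise ValueError(f"unknown energy {name!r}; known: {ENERGY_NAMES}")
    s1 = np.asarray(sigma1, dtype=np.float64)
    s2 = np.asarray(sigma2, dtype=np.float64)
    if np.any(s2 <= 0) or np.any(s1 <= 0):
        raise ValueError(
            f"energy {name} needs positive singular values; the map is "
            "invalid (inverted or collapsed triangle)"
        )
    out = EnergyRegistry[name](s1, s2)
    return float(out) if np.isscalar(sigma1) and np.isscalar(sigma2) else out


# ---------------------------------------------------------------------------
# Frequency bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencySplit:
    """Partition of the triangle set at the median centroid frequency.

    ``low`` holds indices with f_cg strictly below the median, ``high`` the
    rest — so for constant f_cg the low band is empty and the high band is
    the whole mesh.
    """

    median_f: float
    low: np.ndarray
    high: np.ndarray


def split_by_frequency(mesh: TriMesh) -> FrequencySplit:
    """Split triangles at the median of their centroid frequencies."""
    if mesh.n_triangles < 2:
        raise ValueError("need at least 2 triangles to split by frequency")
    f = mesh.f_cg()
    med = float(np.median(f))
    low = np.flatnonzero(f < med)
    high = np.flatnonzero(f >= med)
    return FrequencySplit(median_f=med, low=low, high=high)


def global_distortion(per_triangle_E: np.ndarray, areas: np.ndarray, subset=None) -> float:
    """Area-weighted mean of a local energy over a triangle subset.

    Areas are the source 3D triangle areas.  An empty subset returns NaN
    (callers decide the sentinel; :func:`extract_signature` substitutes the
    full-mesh value).
    """
    E = np.asarray(per_triangle_E, dtype=np.float64)
    a = np.asarray(areas, dtype=np.float64)
    if E.shape != a.shape:
        raise ValueError("energy and area arrays must have the same shape")
    if np.any(a <= 0):
        raise ValueError("triangle areas must be positive")
    if subset is not None:
        E = E[subset]
        a = a[subset]
    if len(E) == 0:
        return float("nan")
    return float(np.dot(E, a) / a.sum())


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistortionSignature:
    """The 16 global distortions (8 energies x low/high frequency band)."""

    values: np.ndarray  # (16,) ordered as FEATURE_NAMES
    median_f: float
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (16,):
            raise ValueError("signature must have exactly 16 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("signature values must be finite")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))

    def __getitem__(self, key: str) -> float:
        return float(self.values[FEATURE_NAMES.index(key)])


def extract_signature(
    mesh: TriMesh,
    emb: PlanarEmbedding | None = None,
    cfg: FlattenConfig = FlattenConfig(),
) -> DistortionSignature:
    """Flatten (if no embedding is given) and aggregate the 16 features.

    All eight energies are evaluated on one length-minimizing flattening.
    If the low band is empty (constant centroid frequency) its features fall
    back to the full-mesh global distortions, with a logged warning.
    """
    if emb is None:
        emb = flatten(mesh, cfg)
    if not emb.is_injective:
        raise ValueError(
            f"embedding has {emb.n_inverted} inverted triangle(s); signature "
            "is only defined for locally injective maps"
        )
    areas = mesh.area3d()
    split = split_by_frequency(mesh)
    if len(split.low) == 0:
        logger.warning(
            "all centroid frequencies equal; low-band features fall back to "
            "the full-mesh global distortions"
        )
    values = []
    for name in ENERGY_NAMES:
        per_tri = evaluate_energy(name, emb.sigma1, emb.sigma2)
        for subset in (split.low, split.high):
            if len(subset) == 0:
                values.append(global_distortion(per_tri, areas))
            else:
                values.append(global_distortion(per_tri, areas, subset))
    return DistortionSignature(
        values=np.asarray(values),
        median_f=split.median_f,
        provenance=f"energy={cfg.optimized_energy},boundary={cfg.boundary}",
    )
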