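"""Seeded synthetic bead envelopes and noisy scattering profiles.

The analysis chain in this package consumes ab initio SAXS envelopes.  For
testing it without instrument data, this module fills simple analytic solids
onto a cubic lattice — deterministically, no randomness — and simulates their
scattering with a seeded Gaussian noise model:

* ``cylinder``      — an elongated rod, the coil-dominated tropoelastin-like
  monomer shape (~18–20 nm long, thin);
* ``curved_rod``    — two rod arms joined at an angle, the bent fibrillin-
  fragment-like shape;
* ``rod_plus_lobe`` — a rod with a spherical lobe on one end cap, the L-shaped
  "long thin region joined to a shorter wider region" complex-like shape;
* ``sphere`` / ``ellipsoid`` — reference solids with known analytic curves.

Noise is zero-mean Gaussian with σ a stated fraction of the forward intensity
I(0) — a deliberately simple stand-in for counting statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .bead_models import LatticeModel, debye_curve, _bisect_spacing
from .saxs_profiles import ScatteringProfile

__all__ = [
    "ShapeSpec",
    "NoiseSpec",
    "make_shape",
    "simulate_profile",
    "rod_fixture",
    "curved_rod_fixture",
    "rod_plus_lobe_fixture",
    "rod_region_map_by_z",
    "match_beads_by_position",
]

_DIM_KEYS = {
    "sphere": ("radius",),
    "ellipsoid": ("a", "b", "c"),
    "cylinder": ("length", "radius"),
    "curved_rod": ("length", "radius", "bend_deg"),
    "rod_plus_lobe": ("length", "radius", "lobe_radius"),
}


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of an analytic solid to be filled onto a lattice.

    ``dimensions`` is keyed per kind (lengths in Å): sphere ``radius``;
    ellipsoid ``a, b, c`` (semi-axes); cylinder ``length, radius``; curved_rod
    ``length, radius, bend_deg`` (total arc length, bend in degrees, 0–90);
    rod_plus_lobe ``length, radius, lobe_radius`` plus optional ``attach_end``
    (+1 = +z end cap, −1 = −z).  ``spacing`` is the lattice constant or
    "auto" with a ``target_count``.  ``seed`` is carried for operations that
    declare randomness (the fill itself uses none).
    """

    kind: str
    dimensions: Mapping[str, float]
    spacing: float | str = "auto"
    target_count: int | None = None
    attach_end: int = +1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _DIM_KEYS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        dims = dict(self.dimensions)
        missing = set(_DIM_KEYS[self.kind]) - set(dims)
        if missing:
            raise ValueError(f"{self.kind} requires dimensions {sorted(missing)}")
        for key in _DIM_KEYS[self.kind]:
            if key == "bend_deg":
                if not 0.0 <= dims[key] <= 90.0:
                    raise ValueError("bend_deg must lie in [0, 90]")
            elif key == "lobe_radius":
                if dims[key] < 0:
                    raise ValueError("lobe_radius must be non-negative")
            elif dims[key] <= 0:
                raise ValueError(f"dimension {key!r} must be positive")
        if self.attach_end not in (+1, -1):
            raise ValueError("attach_end must be +1 or -1")
        object.__setattr__(self, "dimensions", dims)

    def min_extent(self) -> float:
        """Smallest full extent of the solid (diameter for radial dimensions)."""
        d = self.dimensions
        if self.kind == "sphere":
            return 2.0 * d["radius"]
        if self.kind == "ellipsoid":
            return 2.0 * min(d["a"], d["b"], d["c"])
        extents = [d["length"], 2.0 * d["radius"]]
        return min(extents)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level as a fraction of I(0), with its own seed."""

    relative_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be non-negative")


# ---------------------------------------------------------------------------
# Membership predicates
# ---------------------------------------------------------------------------

def _segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    axis = p1 - p0
    length2 = float(axis @ axis)
    t = np.clip((points - p0) @ axis / length2, 0.0, 1.0) if length2 > 0 else 0.0
    nearest = p0 + np.outer(np.atleast_1d(t), axis)
    return np.linalg.norm(points - nearest, axis=1)


def _membership(spec: ShapeSpec, points: np.ndarray) -> np.ndarray:
    d = spec.dimensions
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    if spec.kind == "sphere":
        return np.sum(points ** 2, axis=1) <= d["radius"] ** 2
    if spec.kind == "ellipsoid":
        return ((x / d["a"]) ** 2 + (y / d["b"]) ** 2 + (z / d["c"]) ** 2) <= 1.0
    if spec.kind == "cylinder":
        return (np.abs(z) <= d["length"] / 2.0) & (x * x + y * y <= d["radius"] ** 2)
    if spec.kind == "curved_rod":
        # two arms of length L/2 meeting at the origin at the stated angle
        half = d["length"] / 2.0
        theta = math.radians(d["bend_deg"])
        end_a = np.array([0.0, 0.0, half])
        end_b = half * np.array([math.sin(theta), 0.0, -math.cos(theta)])
        origin = np.zeros(3)
        dist = np.minimum(_segment_distance(points, origin, end_a),
                          _segment_distance(points, origin, end_b))
        return dist <= d["radius"]
    if spec.kind == "rod_plus_lobe":
        inside_rod = (np.abs(z) <= d["length"] / 2.0) & (x * x + y * y <= d["radius"] ** 2)
        cap = np.array([0.0, 0.0, spec.attach_end * d["length"] / 2.0])
        inside_lobe = np.sum((points - cap) ** 2, axis=1) <= d["lobe_radius"] ** 2
        return inside_rod | inside_lobe
    raise AssertionError(spec.kind)


def _bounding_radius(spec: ShapeSpec) -> float:
    d = spec.dimensions
    if spec.kind == "sphere":
        return d["radius"]
    if spec.kind == "ellipsoid":
        return max(d["a"], d["b"], d["c"])
    if spec.kind == "cylinder":
        return math.hypot(d["length"] / 2.0, d["radius"])
    if spec.kind == "curved_rod":
        return d["length"] / 2.0 + d["radius"]
    return d["length"] / 2.0 + max(d["radius"], d["lobe_radius"])


def _fill(spec: ShapeSpec, spacing: float) -> np.ndarray:
    """Lattice indices (sorted z, y, x) of points inside the analytic solid."""
    extent = int(math.ceil(_bounding_radius(spec) / spacing)) + 1
    rng = np.arange(-extent, extent + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    inside = _membership(spec, spacing * ijk.astype(float))
    ijk = ijk[inside]
    order = np.lexsort((ijk[:, 0], ijk[:, 1], ijk[:, 2]))
    return ijk[order]


def make_shape(spec: ShapeSpec) -> LatticeModel:
    """Deterministic lattice fill of an analytic solid.

    The lattice is anchored at the solid's symmetry origin.  Numeric spacings
    must not exceed a third of the smallest extent (coarser grids cannot
    represent the solid); ``spacing="auto"`` with a ``target_count`` instead
    bisects the spacing until the bead count is within 5% of the target.
    """
    if spec.spacing == "auto":
        target = spec.target_count
        if target is None:
            raise ValueError('spacing="auto" requires target_count')
        if target < 10:
            raise ValueError("target_count must be at least 10")
        spacing = _bisect_spacing(lambda a: _fill(spec, a).shape[0],
                                  lo=spec.min_extent() / 20.0,
                                  hi=spec.min_extent() / 2.0,
                                  target=target)
    else:
        spacing = float(spec.spacing)
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        if spacing > spec.min_extent() / 3.0:
            raise ValueError(
                f"spacing {spacing:g} too coarse for smallest extent "
                f"{spec.min_extent():g} (must be <= extent/3)")
    ijk = _fill(spec, spacing)
    if ijk.shape[0] < 30:
        raise ValueError(f"shape yields only {ijk.shape[0]} beads (< 30); "
                         "refine the spacing or enlarge the solid")
    return LatticeModel(centres=spacing * ijk.astype(float),
                        bead_radius=0.5 * spacing,
                        label=f"{spec.kind}", spacing=spacing,
                        origin=np.zeros(3))


def simulate_profile(model, q_max: float, n_q: int,
                     noise: NoiseSpec = NoiseSpec()) -> ScatteringProfile:
    """Debye curve on a uniform q grid (0, q_max] plus seeded Gaussian noise.

    σ per point is ``relative_sigma · I(0)`` (I(0) = N² for point beads); the
    σ column reports that true value.  ``relative_sigma = 0`` returns the exact
    curve with no σ column.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    if n_q < 20:
        raise ValueError("n_q must be at least 20")
    q = np.linspace(q_max / n_q, q_max, n_q)
    clean = debye_curve(model, q)
    if noise.relative_sigma == 0:
        return ScatteringProfile(q, clean.intensity, None,
                                 label=f"sim:{model.label}")
    i0 = float(model.n_beads) ** 2
    sigma = noise.relative_sigma * i0
    rng = np.random.default_rng(noise.seed)
    noisy = clean.intensity + rng.normal(0.0, sigma, size=n_q)
    return ScatteringProfile(q, noisy, np.full(n_q, sigma),
                             label=f"sim:{model.label}:seed{noise.seed}")


# ---------------------------------------------------------------------------
# Packaged comparison fixtures
# ---------------------------------------------------------------------------

#: Shared lattice constant of the packaged rod / composite comparison pair.
#: 9 Å puts the free rod near the bead count of the tropoelastin envelope
#: (168 beads) while keeping the composite eigenproblem small.
FIXTURE_SPACING = 9.0

ROD_LENGTH = 180.0        # Å — ~18 nm elongated monomer-like rod
ROD_RADIUS = 15.0         # Å
LOBE_RADIUS = 35.0        # Å — the "shorter, wider" end lobe of the complex
CURVED_LENGTH = 150.0     # Å — matches the bent-fragment maximum dimension scale
CURVED_RADIUS = 14.0      # Å
CURVED_BEND_DEG = 40.0


def rod_fixture(spacing: float = FIXTURE_SPACING) -> LatticeModel:
    """Elongated free rod (cylinder 180 × 15 Å)."""
    return make_shape(ShapeSpec("cylinder",
                                {"length": ROD_LENGTH, "radius": ROD_RADIUS},
                                spacing=spacing))


def curved_rod_fixture(spacing: float = FIXTURE_SPACING) -> LatticeModel:
    """Bent rod (150 Å arc, 14 Å radius, 40° bend)."""
    return make_shape(ShapeSpec("curved_rod",
                                {"length": CURVED_LENGTH, "radius": CURVED_RADIUS,
                                 "bend_deg": CURVED_BEND_DEG},
                                spacing=spacing))


def rod_plus_lobe_fixture(spacing: float = FIXTURE_SPACING,
                          lobe_radius: float = LOBE_RADIUS) -> LatticeModel:
    """The rod of :func:`rod_fixture` with a spherical lobe on its +z end cap."""
    return make_shape(ShapeSpec("rod_plus_lobe",
                                {"length": ROD_LENGTH, "radius": ROD_RADIUS,
                                 "lobe_radius": lobe_radius},
                                spacing=spacing))


def rod_region_map_by_z(rod: LatticeModel, end_depth: float = 30.0):
    """Three z-bands of a rod: free end, middle, junction (+z) end.

    Bead ordering is lexicographic in (z, y, x), so z bands are contiguous
    1-based index ranges.  ``end_depth`` is the band thickness in Å.
    """
    from .mobility import RegionMap
    z = rod.centres[:, 2]
    zmin, zmax = z.min(), z.max()
    n = rod.n_beads
    free_last = int(np.sum(z <= zmin + end_depth))
    junction_first = n - int(np.sum(z >= zmax - end_depth)) + 1
    return RegionMap((("free_end", 1, free_last),
                      ("middle", free_last + 1, junction_first - 1),
                      ("junction_end", junction_first, n)))


def match_beads_by_position(component: LatticeModel, complex_: LatticeModel,
                            tol: float = 1e-6) -> dict[int, int]:
    """Exact coordinate-identity bead mapping (1-based component → complex).

    Intended for fixture pairs built on the same lattice anchor, where the
    component's beads are a literal subset of the complex's; raises if any
    component bead has no counterpart within ``tol``.
    """
    tree = cKDTree(complex_.centres)
    dist, idx = tree.query(component.centres, k=1)
    if np.any(dist > tol):
        raise ValueError("component beads are not a coordinate subset of the complex")
    return {i + 1: int(j) + 1 for i, j in enumerate(idx)}
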