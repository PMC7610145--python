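"""Region-wise mobility analysis of per-bead RMSF profiles.

Lattice bead numbering gives each envelope a reproducible 1-based index along
the structure, so named regions (coil, spur, head, tail, base, extension, ...)
are simple index ranges.  This module segments RMSF profiles into such
regions, locates pivots (interior mobility minima about which bending occurs),
and compares the mobility of a free component against the same beads inside a
complex — the readout behind "cross-linking stabilises the component" claims.

Because the absolute fluctuation scale of an elastic network is arbitrary
(γ and temperature are unknown for an envelope), comparisons normalise each
profile by its own structure-wide mean RMSF before forming ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "RegionMap",
    "MobilityProfile",
    "RegionStats",
    "RegionComparison",
    "StabilizationReport",
    "TROPOELASTIN_REGIONS",
    "FIBRILLIN_PF2_REGIONS",
    "COMPLEX_REGIONS",
    "segment_regions",
    "find_pivots",
    "compare_mobility",
    "export_colored_model",
]


@dataclass(frozen=True)
class RegionMap:
    """Ordered named bead-index ranges, 1-based inclusive, non-overlapping."""

    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        covered: list[tuple[int, int]] = []
        norm = []
        for name, first, last in self.regions:
            if name in seen:
                raise ValueError(f"duplicate region name {name!r}")
            seen.add(name)
            first, last = int(first), int(last)
            if first < 1 or last < first:
                raise ValueError(f"bad range {first}-{last} for region {name!r}")
            for lo, hi in covered:
                if first <= hi and last >= lo:
                    raise ValueError(f"region {name!r} overlaps an earlier region")
            covered.append((first, last))
            norm.append((str(name), first, last))
        object.__setattr__(self, "regions", tuple(norm))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "RegionMap":
        """Build from config-style ``{"coil": "1-110", ...}`` entries."""
        regions = []
        for name, span in mapping.items():
            first, _, last = str(span).partition("-")
            regions.append((name, int(first), int(last) if last else int(first)))
        return cls(tuple(regions))

    @property
    def max_bead(self) -> int:
        return max(last for _, _, last in self.regions)

    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.regions)

    def beads(self, name: str) -> np.ndarray:
        """1-based bead indices of a named region."""
        for rname, first, last in self.regions:
            if rname == name:
                return np.arange(first, last + 1)
        raise KeyError(name)


#: Tropoelastin envelope segmentation (168 beads): elongated N-terminal coil,
#: spur, and the C-terminal foot region protruding from the bridge.
TROPOELASTIN_REGIONS = RegionMap((("coil", 1, 110), ("spur", 111, 133),
                                  ("c_terminal", 134, 168)))

#: Fibrillin-1 PF2 fragment envelope segmentation (127 beads): elongated tail
#: (lower + upper) capped by the bulbous head where TB2 and the cross-link
#: glutamine reside.
FIBRILLIN_PF2_REGIONS = RegionMap((("lower_tail", 1, 39), ("upper_tail", 40, 77),
                                   ("head", 78, 128)))

#: Cross-linked complex envelope segmentation (226 beads): a large immobile
#: base (upper/lower) trailed by a thinner extension (upper/lower).
COMPLEX_REGIONS = RegionMap((("upper_base", 1, 85), ("lower_base", 86, 168),
                             ("upper_extension", 169, 181),
                             ("lower_extension", 182, 226)))


@dataclass(frozen=True)
class MobilityProfile:
    """Per-bead RMSF (Å) with optional named-region segmentation."""

    rmsf: np.ndarray
    modes_used: tuple[int, ...] = ()
    region_map: RegionMap | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.rmsf, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("rmsf must be a non-empty 1D array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("rmsf values must be finite and non-negative")
        object.__setattr__(self, "rmsf", values)
        object.__setattr__(self, "modes_used", tuple(self.modes_used))

    @property
    def bead_count(self) -> int:
        return self.rmsf.size

    def normalised(self) -> np.ndarray:
        """RMSF divided by the structure-wide mean (dimensionless)."""
        mean = float(self.rmsf.mean())
        if mean <= 0:
            raise ValueError("cannot normalise a profile with non-positive mean RMSF")
        return self.rmsf / mean

    def write_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([np.arange(1, self.bead_count + 1),
                                          self.rmsf]),
                   delimiter=",", header="bead,rmsf", comments="", fmt="%d,%.8g")

    @classmethod
    def read_csv(cls, path) -> "MobilityProfile":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(rmsf=data[:, 1])


@dataclass(frozen=True)
class RegionStats:
    name: str
    n_beads: int
    mean: float
    minimum: float
    maximum: float
    argmin_bead: int     # 1-based; ties -> lowest index
    argmax_bead: int


@dataclass(frozen=True)
class RegionComparison:
    name: str
    component_mean_norm: float
    complex_mean_norm: float
    ratio: float                 # complex / component, normalised scales
    verdict: str                 # stabilised | mobilised | unchanged


@dataclass(frozen=True)
class StabilizationReport:
    """Region-wise component-vs-complex mobility comparison."""

    component_regions: dict[str, RegionStats]
    complex_regions: dict[str, RegionStats]
    comparisons: dict[str, RegionComparison]
    threshold: float
    component_mean_rmsf: float
    complex_mean_rmsf: float

    def verdicts(self) -> dict[str, str]:
        return {name: c.verdict for name, c in self.comparisons.items()}

    def summary(self) -> str:
        lines = [
            "Component vs complex mobility",
            "-----------------------------",
            f"threshold: {self.threshold:g} "
            f"(stabilised < {1 - self.threshold:g}, mobilised > {1 + self.threshold:g})",
            f"{'region':<18}{'comp':>8}{'cplx':>8}{'ratio':>8}  verdict",
        ]
        for name, c in self.comparisons.items():
            lines.append(f"{name:<18}{c.component_mean_norm:8.3f}"
                         f"{c.complex_mean_norm:8.3f}{c.ratio:8.3f}  {c.verdict}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "component_mean_rmsf": self.component_mean_rmsf,
            "complex_mean_rmsf": self.complex_mean_rmsf,
            "regions": {
                name: {
                    "component_mean_norm": c.component_mean_norm,
                    "complex_mean_norm": c.complex_mean_norm,
                    "ratio": c.ratio,
                    "verdict": c.verdict,
                } for name, c in self.comparisons.items()
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _region_stats(name: str, beads: np.ndarray, values: np.ndarray) -> RegionStats:
    sub = values[beads - 1]
    return RegionStats(
        name=name, n_beads=beads.size, mean=float(sub.mean()),
        minimum=float(sub.min()), maximum=float(sub.max()),
        argmin_bead=int(beads[int(np.argmin(sub))]),
        argmax_bead=int(beads[int(np.argmax(sub))]))


def segment_regions(profile: MobilityProfile,
                    region_map: RegionMap | None = None) -> dict[str, RegionStats]:
    """Per-region mean/min/max RMSF and the beads attaining each extremum.

    Beads not covered by any region are summarised under ``"_unassigned"``.
    """
    rmap = region_map if region_map is not None else profile.region_map
    if rmap is None:
        raise ValueError("no region map supplied")
    n = profile.bead_count
    if rmap.max_bead > n:
        raise ValueError(f"region map covers bead #{rmap.max_bead} "
                         f"but the profile has only {n} beads")
    out: dict[str, RegionStats] = {}
    assigned = np.zeros(n, dtype=bool)
    for name, first, last in rmap.regions:
        beads = np.arange(first, last + 1)
        assigned[first - 1:last] = True
        out[name] = _region_stats(name, beads, profile.rmsf)
    if not assigned.all():
        beads = np.flatnonzero(~assigned) + 1
        out["_unassigned"] = _region_stats("_unassigned", beads, profile.rmsf)
    return out


def find_pivots(profile: MobilityProfile, window: int = 7) -> list[int]:
    """Interior local minima of the smoothed RMSF profile (1-based beads).

    The profile is smoothed with a centred moving average of ``window`` beads
    to suppress lattice-level jitter; plateau minima report their centre bead.
    """
    n = profile.bead_count
    if n < 2 * window + 1:
        raise ValueError("profile too short for the smoothing window")
    kernel = np.ones(window) / window
    smooth = np.convolve(profile.rmsf, kernel, mode="valid")
    offset = window // 2                     # smooth[i] is centred on bead i+offset
    pivots: list[int] = []
    i = 1
    while i < smooth.size - 1:
        if smooth[i] < smooth[i - 1]:
            j = i
            while j + 1 < smooth.size and smooth[j + 1] == smooth[i]:
                j += 1
            if j + 1 < smooth.size and smooth[j + 1] > smooth[i]:
                centre = (i + j) // 2
                pivots.append(centre + offset + 1)
                i = j + 1
                continue
        i += 1
    return pivots


def _as_mapping_arrays(mapping) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(mapping, Mapping):
        comp = np.array(sorted(mapping), dtype=int)
        cplx = np.array([mapping[k] for k in sorted(mapping)], dtype=int)
    else:
        arr = np.asarray(mapping, dtype=int)
        comp, cplx = arr[:, 0], arr[:, 1]
    if comp.size == 0:
        raise ValueError("empty bead mapping")
    if np.unique(cplx).size != cplx.size or np.unique(comp).size != comp.size:
        raise ValueError("bead mapping must be injective")
    return comp, cplx


def compare_mobility(component: MobilityProfile, complex_: MobilityProfile,
                     mapping, threshold: float = 0.2) -> StabilizationReport:
    """Compare region mobility of a free component against the complex.

    ``mapping`` gives the component-bead → complex-bead correspondence (dict or
    (M, 2) array, 1-based).  Each profile is normalised by its own
    structure-wide mean RMSF, removing the arbitrary amplitude scale; per
    region the ratio of normalised complex to component means yields a verdict:
    "stabilised" below ``1 − threshold``, "mobilised" above ``1 + threshold``,
    otherwise "unchanged".
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    comp_beads, cplx_beads = _as_mapping_arrays(mapping)
    if comp_beads.max() > component.bead_count or comp_beads.min() < 1:
        raise ValueError("mapping references beads outside the component profile")
    if cplx_beads.max() > complex_.bead_count or cplx_beads.min() < 1:
        raise ValueError("mapping references beads outside the complex profile")

    comp_norm = component.normalised()
    cplx_norm = complex_.normalised()
    to_complex = dict(zip(comp_beads.tolist(), cplx_beads.tolist()))

    rmap = component.region_map
    if rmap is None:
        rmap = RegionMap((("all", 1, component.bead_count),))
    comp_stats = segment_regions(component, rmap)

    comparisons: dict[str, RegionComparison] = {}
    cplx_stats: dict[str, RegionStats] = {}
    for name, first, last in rmap.regions:
        mapped = [(b, to_complex[b]) for b in range(first, last + 1) if b in to_complex]
        if not mapped:
            continue
        cb = np.array([m[0] for m in mapped])
        xb = np.array([m[1] for m in mapped])
        comp_mean = float(comp_norm[cb - 1].mean())
        cplx_mean = float(cplx_norm[xb - 1].mean())
        if comp_mean <= 0:
            raise ValueError(f"region {name!r} has non-positive mean RMSF")
        ratio = cplx_mean / comp_mean
        if ratio < 1.0 - threshold:
            verdict = "stabilised"
        elif ratio > 1.0 + threshold:
            verdict = "mobilised"
        else:
            verdict = "unchanged"
        comparisons[name] = RegionComparison(
            name=name, component_mean_norm=comp_mean,
            complex_mean_norm=cplx_mean, ratio=ratio, verdict=verdict)
        cplx_stats[name] = _region_stats(name, xb, complex_.rmsf)
    if not comparisons:
        raise ValueError("mapping does not touch any region of the component")
    return StabilizationReport(
        component_regions=comp_stats, complex_regions=cplx_stats,
        comparisons=comparisons, threshold=threshold,
        component_mean_rmsf=float(component.rmsf.mean()),
        complex_mean_rmsf=float(complex_.rmsf.mean()))


def export_colored_model(model, profile: MobilityProfile, path) -> None:
    """Write a dummy-atom PDB coloured by mobility via the B-factor column.

    RMSF is affinely rescaled to [0, 100] (a constant profile maps to 0); the
    affine parameters go to a ``<path>.json`` sidecar so values are
    recoverable: ``rmsf = b_factor · scale + offset``.
    """
    from .bead_models import write_bead_pdb
    if profile.bead_count != model.n_beads:
        raise ValueError("profile length does not match the bead count")
    lo, hi = float(profile.rmsf.min()), float(profile.rmsf.max())
    if hi > lo:
        b = (profile.rmsf - lo) / (hi - lo) * 100.0
        scale = (hi - lo) / 100.0
    else:
        b = np.zeros(profile.bead_count)
        scale = 0.0
    write_bead_pdb(model, path, bfactors=b)
    sidecar = {"scale": scale, "offset": lo, "rmsf_min": lo, "rmsf_max": hi,
               "convention": "rmsf = b_factor * scale + offset"}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
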