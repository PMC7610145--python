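"""Anisotropic elastic-network model on lattice bead envelopes.

Beads within a cutoff distance are joined by identical harmonic springs of
stiffness γ.  At equilibrium the potential is quadratic, ``V(u) = ½ uᵀ H u``,
with the Hessian built from 3×3 blocks

    H_ij = −(γ / r_ij²) · d_ij ⊗ d_ij          (i ≠ j, edge)
    H_ii = −Σ_{j≠i} H_ij

where ``d_ij`` is the equilibrium centre-difference vector.  The eigenvectors
``u_k`` of H form an orthonormal basis of normal modes with frequencies
``ω_k = √λ_k``; a connected, non-collinear network has exactly six zero modes
(rigid translations and rotations).  Low-frequency modes dominate the motion
because mode amplitudes scale as 1/ω, so per-bead fluctuations are

    RMSF_i = T · sqrt( Σ_k (1/ω_k²) |u_k[i]|² )

with T a global temperature scale (kT/γ = 1 internally; absolute Å values
require a calibration the envelope alone cannot supply — relative profiles are
the meaningful readout).

All masses are uniform: envelope beads are identical dummy atoms, so the mass
weighting is a constant absorbed into γ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .bead_models import LatticeModel, model_geometry
from .mobility import MobilityProfile

__all__ = [
    "LatticeNetwork",
    "ModeSet",
    "DeformationTrajectory",
    "DisconnectedNetworkError",
    "build_network",
    "build_hessian",
    "compute_modes",
    "rmsf",
    "combine_modes",
    "ElasticNetworkModel",
    "NormalModeResults",
]

#: Eigenvalues below this fraction of the largest are treated as zero modes.
ZERO_MODE_RTOL = 1e-8


class DisconnectedNetworkError(ValueError):
    """Raised when the spring network splits into several components."""

    def __init__(self, component_sizes):
        self.component_sizes = sorted(component_sizes, reverse=True)
        super().__init__(
            "elastic network is disconnected (component sizes: "
            + " + ".join(str(s) for s in self.component_sizes)
            + "); increase the cutoff factor or check the envelope")


@dataclass(frozen=True)
class LatticeNetwork:
    """A lattice bead model plus its spring connectivity."""

    model: LatticeModel
    cutoff: float
    gamma: float
    edges: np.ndarray      # (E, 2) with i < j

    @property
    def n_beads(self) -> int:
        return self.model.n_beads

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_beads, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


@dataclass(frozen=True)
class ModeSet:
    """Eigen-decomposition of an elastic-network Hessian.

    ``eigenvalues`` are ω², ascending; ``eigenvectors`` holds the orthonormal
    modes as columns.  "Mode k" (1-based) in every downstream API means the
    k-th *non-zero* mode in ascending eigenvalue order.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    temperature_scale: float = 1.0

    @property
    def n_beads(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_nonzero(self) -> int:
        return self.eigenvalues.size - self.n_zero

    def nonzero_index(self, mode: int) -> int:
        """Column index of 1-based non-zero mode number ``mode``."""
        if not 1 <= mode <= self.n_nonzero:
            raise IndexError(f"mode {mode} outside 1..{self.n_nonzero}")
        return self.n_zero + mode - 1

    def mode_vector(self, mode: int) -> np.ndarray:
        return self.eigenvectors[:, self.nonzero_index(mode)]

    def mode_frequency(self, mode: int) -> float:
        return math.sqrt(self.eigenvalues[self.nonzero_index(mode)])


@dataclass(frozen=True)
class DeformationTrajectory:
    """Bead-coordinate snapshots of a combined low-mode oscillation."""

    frames: np.ndarray          # (n_frames, N, 3), frame 0 = equilibrium
    modes_used: tuple[int, ...]
    amplitude_rule: str

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def write_pdb(self, model: LatticeModel, path) -> None:
        """Write the trajectory as a multi-MODEL dummy-atom PDB."""
        with open(path, "w") as fh:
            fh.write(f"REMARK 265 Dummy atom radius : {model.bead_radius:.2f}\n")
            for t in range(self.n_frames):
                fh.write(f"MODEL     {t + 1:4d}\n")
                for idx, (x, y, z) in enumerate(self.frames[t], start=1):
                    fh.write(f"ATOM  {idx:5d}  CA  DUM A{idx:4d}    "
                             f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# Network and Hessian construction
# ---------------------------------------------------------------------------

def build_network(model: LatticeModel, cutoff_factor: float = 1.6,
                  gamma: float = 1.0) -> LatticeNetwork:
    """Connect bead pairs within ``cutoff_factor × spacing``.

    The default 1.6 captures nearest (a) and second-nearest (√2·a ≈ 1.414a)
    cubic-lattice neighbours while excluding third-nearest (√3·a ≈ 1.732a).
    Raises :class:`DisconnectedNetworkError` (with component sizes) if the
    resulting graph is not a single component.
    """
    if not 1.0 < cutoff_factor < 2.0:
        raise ValueError("cutoff_factor must lie in (1, 2)")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    cutoff = cutoff_factor * model.spacing
    pairs = cKDTree(model.centres).query_pairs(r=cutoff, output_type="ndarray")
    edges = np.sort(pairs, axis=1)
    n = model.n_beads
    adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp != 1:
        raise DisconnectedNetworkError(np.bincount(labels).tolist())
    return LatticeNetwork(model=model, cutoff=cutoff, gamma=gamma, edges=edges)


def build_hessian(network: LatticeNetwork) -> np.ndarray:
    """Assemble the symmetric 3N×3N elastic-network Hessian."""
    n = network.n_beads
    centres = network.model.centres
    i_idx, j_idx = network.edges[:, 0], network.edges[:, 1]
    d = centres[j_idx] - centres[i_idx]
    r2 = np.sum(d * d, axis=1)
    blocks = -(network.gamma / r2)[:, None, None] * d[:, :, None] * d[:, None, :]

    h = np.zeros((n, 3, n, 3))
    np.add.at(h, (i_idx, slice(None), j_idx, slice(None)), blocks)
    np.add.at(h, (j_idx, slice(None), i_idx, slice(None)), blocks)
    np.add.at(h, (i_idx, slice(None), i_idx, slice(None)), -blocks)
    np.add.at(h, (j_idx, slice(None), j_idx, slice(None)), -blocks)
    h = h.reshape(3 * n, 3 * n)
    return 0.5 * (h + h.T)      # exact symmetry against accumulation round-off


def compute_modes(hessian: np.ndarray, n_modes="all",
                  temperature_scale: float = 1.0,
                  expected_n_zero: int | None = None) -> ModeSet:
    """Dense symmetric eigendecomposition with zero-mode bookkeeping.

    ``n_modes`` may be "all" or a count of non-zero modes to retain (the six
    lowest eigenpairs are always kept alongside to classify rigid-body modes).
    ``expected_n_zero`` optionally asserts the rigid-body count — pass 6 for a
    network known to be connected and non-collinear.
    """
    h = np.asarray(hessian, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1] or h.shape[0] % 3:
        raise ValueError("hessian must be square with size 3N")
    if not np.allclose(h, h.T, atol=1e-10 * max(1.0, np.abs(h).max())):
        raise ValueError("hessian must be symmetric")
    dim = h.shape[0]
    if n_modes == "all":
        eigenvalues, eigenvectors = linalg.eigh(h)
    else:
        upper = min(int(n_modes) + 6, dim)
        eigenvalues, eigenvectors = linalg.eigh(h, subset_by_index=[0, upper - 1])
    scale = max(float(eigenvalues[-1]), float(np.abs(h).max()), 1e-300)
    n_zero = int(np.sum(eigenvalues < ZERO_MODE_RTOL * scale))
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    if expected_n_zero is not None and n_zero != expected_n_zero:
        raise ValueError(
            f"found {n_zero} zero modes, expected {expected_n_zero}: "
            "network construction or numerics are at fault")
    return ModeSet(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                   n_zero=n_zero, temperature_scale=temperature_scale)


# ---------------------------------------------------------------------------
# Fluctuations and trajectories
# ---------------------------------------------------------------------------

def _resolve_subset(modes: ModeSet, mode_subset) -> list[int]:
    if mode_subset is None:
        subset = list(range(1, min(6, modes.n_nonzero) + 1))
    else:
        subset = [int(k) for k in mode_subset]
    if not subset:
        raise ValueError("empty mode subset")
    for k in subset:
        if k < 1:
            raise ValueError("mode numbers are 1-based non-zero modes; "
                             "zero (rigid-body) modes cannot be requested")
        modes.nonzero_index(k)
    return subset


def rmsf(modes: ModeSet, mode_subset=None,
         region_map=None) -> MobilityProfile:
    """Per-bead root mean square fluctuation over a subset of non-zero modes.

    Default subset: non-zero modes 1–6 (the low-frequency motions that dominate
    the dynamics).  Bead numbering is identical to the lattice-model ordering.
    """
    subset = _resolve_subset(modes, mode_subset)
    n = modes.n_beads
    total = np.zeros(n)
    for k in subset:
        col = modes.eigenvectors[:, modes.nonzero_index(k)].reshape(n, 3)
        lam = modes.eigenvalues[modes.nonzero_index(k)]
        total += np.sum(col * col, axis=1) / lam
    values = modes.temperature_scale * np.sqrt(total)
    return MobilityProfile(rmsf=values, modes_used=tuple(subset),
                           region_map=region_map)


def combine_modes(modes: ModeSet, equilibrium: LatticeModel, k: int = 6,
                  amplitude_rule: str = "inverse_frequency",
                  n_frames: int = 20, scale: float | None = None) -> DeformationTrajectory:
    """Superpose the k lowest non-zero modes into a periodic deformation movie.

    Mode k′ (1-based within the subset) oscillates with amplitude
    ``scale/ω_k′`` (or ``scale`` under the "equal" rule) through k′ full cycles
    per trajectory period, so frame 0 is the equilibrium and the time-averaged
    squared displacement reproduces the subset RMSF² profile exactly.  When
    ``scale`` is None it is set so the peak bead displacement equals
    0.05 × Dmax of the equilibrium model.
    """
    if amplitude_rule not in ("inverse_frequency", "equal"):
        raise ValueError("amplitude_rule must be 'inverse_frequency' or 'equal'")
    if k > modes.n_nonzero:
        raise ValueError(f"k={k} exceeds the {modes.n_nonzero} non-zero modes")
    if n_frames < 2 * k + 2:
        raise ValueError("n_frames too small to resolve the highest harmonic")
    n = modes.n_beads
    amps, vecs = [], []
    for mode in range(1, k + 1):
        omega = modes.mode_frequency(mode)
        amps.append(1.0 / omega if amplitude_rule == "inverse_frequency" else 1.0)
        vecs.append(modes.eigenvectors[:, modes.nonzero_index(mode)].reshape(n, 3))
    t = np.arange(n_frames)
    disp = np.zeros((n_frames, n, 3))
    for mode_i, (a, v) in enumerate(zip(amps, vecs), start=1):
        phase = np.sin(2.0 * np.pi * mode_i * t / n_frames)
        disp += a * phase[:, None, None] * v[None, :, :]
    if scale is None:
        peak = np.max(np.linalg.norm(disp, axis=2))
        target = 0.05 * model_geometry(equilibrium).dmax
        scale = target / peak if peak > 0 else 1.0
    frames = equilibrium.centres[None, :, :] + scale * disp
    return DeformationTrajectory(frames=frames,
                                 modes_used=tuple(range(1, k + 1)),
                                 amplitude_rule=amplitude_rule)


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class ElasticNetworkModel:
    """Anisotropic network model of a lattice bead envelope.

    Parameters
    ----------
    model : LatticeModel
        Beads on a regular cubic lattice (see ``resample_to_lattice`` or
        ``synthetic_shapes.make_shape``).
    cutoff_factor : float
        Interaction cutoff as a multiple of the lattice spacing; the default
        1.6 spans nearest and second-nearest neighbours.
    gamma : float
        Uniform spring constant (energy/Å² in internal units).

    Examples
    --------
    >>> enm = ElasticNetworkModel(lattice)          # doctest: +SKIP
    >>> res = enm.fit()                             # doctest: +SKIP
    >>> res.rmsf().rmsf                             # doctest: +SKIP
    """

    def __init__(self, model: LatticeModel, cutoff_factor: float = 1.6,
                 gamma: float = 1.0):
        self.model = model
        self.network = build_network(model, cutoff_factor=cutoff_factor, gamma=gamma)

    def fit(self, n_modes="all", temperature_scale: float = 1.0) -> "NormalModeResults":
        """Diagonalise the Hessian and return a results object."""
        hessian = build_hessian(self.network)
        modes = compute_modes(hessian, n_modes=n_modes,
                              temperature_scale=temperature_scale)
        return NormalModeResults(self, modes)


class NormalModeResults:
    """Normal modes, fluctuations and trajectories of a fitted network."""

    def __init__(self, model: ElasticNetworkModel, modes: ModeSet):
        self.model = model
        self.modes = modes

    def rmsf(self, mode_subset=None, region_map=None) -> MobilityProfile:
        return rmsf(self.modes, mode_subset=mode_subset, region_map=region_map)

    def trajectory(self, k: int = 6, **kwargs) -> DeformationTrajectory:
        return combine_modes(self.modes, self.model.model, k=k, **kwargs)

    def summary(self) -> str:
        m = self.modes
        prof = self.rmsf()
        lines = [
            "Elastic network normal mode analysis",
            "------------------------------------",
            f"beads                {m.n_beads}",
            f"edges                {self.model.network.edges.shape[0]}",
            f"cutoff               {self.model.network.cutoff:.3f} A",
            f"gamma                {self.model.network.gamma:g}",
            f"zero modes           {m.n_zero}",
            "lowest nonzero w^2   "
            + " ".join(f"{m.eigenvalues[m.nonzero_index(k)]:.5g}"
                       for k in range(1, min(6, m.n_nonzero) + 1)),
            f"RMSF (modes {prof.modes_used[0]}-{prof.modes_used[-1]}): "
            f"min {prof.rmsf.min():.4g} at bead #{int(np.argmin(prof.rmsf)) + 1}, "
            f"max {prof.rmsf.max():.4g} at bead #{int(np.argmax(prof.rmsf)) + 1}",
        ]
        return "\n".join(lines)
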