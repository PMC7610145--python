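"""Small-angle X-ray scattering profile analysis.

A measured SAXS curve ``I(q)`` encodes the rotationally averaged, low-resolution
shape of a particle in solution.  This module provides the standard 1D analysis
chain used to characterise such curves:

* :func:`guinier_fit` — low-``q`` linear fit of ``ln I`` versus ``q²`` giving the
  radius of gyration ``Rg`` and forward intensity ``I(0)``;
* :func:`ift_pr` — regularised indirect Fourier transform giving the
  pair-distance distribution function ``P(r)`` and the maximum particle
  dimension ``Dmax``;
* :func:`fit_model_to_profile` — closed-form scale + background fit of a model
  curve against experimental data with a reduced χ² score.

All momentum transfers are in reciprocal ångström and all distances in
ångström.  Profiles recorded in reciprocal nanometre are converted at the file
boundary (``read_profile(..., dialect="nanometre_inverse")``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ScatteringProfile",
    "GuinierResult",
    "PairDistribution",
    "ProfileFit",
    "GuinierError",
    "IFTError",
    "read_profile",
    "write_profile",
    "guinier_fit",
    "ift_pr",
    "fit_model_to_profile",
]

logger = logging.getLogger(__name__)

#: Assumed relative uncertainty when a profile carries no σ column.  Using a
#: relative (rather than unit) weight keeps every χ² quantity invariant under
#: rescaling of the intensities, which an arbitrary-units SAXS curve demands.
ASSUMED_RELATIVE_SIGMA = 0.01


class GuinierError(ValueError):
    """Raised when a Guinier fit cannot be performed or does not converge."""


class IFTError(ValueError):
    """Raised when the indirect Fourier transform fails."""


@dataclass(frozen=True)
class ScatteringProfile:
    """A 1D SAXS curve: I(q) with optional 1-σ uncertainties.

    Parameters
    ----------
    q : array
        Momentum transfer, reciprocal Å, strictly increasing and positive.
    intensity : array
        Scattered intensity per point, arbitrary units.
    sigma : array, optional
        1-standard-deviation uncertainty per point; strictly positive.
    label : str
        Free-text identifier.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.shape != q.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if q.size and (np.any(q <= 0) or np.any(np.diff(q) <= 0)):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s <= 0) or not np.all(np.isfinite(s)):
                raise ValueError("sigma must be strictly positive and finite")

    def __len__(self) -> int:
        return self.q.size

    def effective_sigma(self) -> tuple[np.ndarray, bool]:
        """Return per-point σ and whether it was assumed rather than measured.

        Absent σ is replaced by ``ASSUMED_RELATIVE_SIGMA · |I|`` (floored at the
        smallest positive value to keep weights finite on I = 0 points).
        """
        if self.sigma is not None:
            return self.sigma, False
        mag = np.abs(self.intensity)
        floor = mag[mag > 0].min() if np.any(mag > 0) else 1.0
        return ASSUMED_RELATIVE_SIGMA * np.maximum(mag, floor), True


@dataclass(frozen=True)
class GuinierResult:
    """Result of a self-consistent Guinier fit."""

    rg: float
    i0: float
    q_window: tuple[float, float]
    n_points: int
    fit_r2: float
    qrg_limit: float = 1.0
    sigma_assumed: bool = False

    def summary(self) -> str:
        lo, hi = self.q_window
        lines = [
            "Guinier fit",
            "-----------",
            f"Rg           {self.rg:10.3f} A",
            f"I(0)         {self.i0:10.4g}",
            f"q window     [{lo:.5f}, {hi:.5f}] 1/A  ({self.n_points} pts)",
            f"qmax*Rg      {hi * self.rg:10.3f}  (limit {self.qrg_limit:g})",
            f"fit R^2      {self.fit_r2:10.6f}",
        ]
        if self.sigma_assumed:
            lines.append("(no experimental sigma; 1% relative errors assumed)")
        return "\n".join(lines)


@dataclass(frozen=True)
class PairDistribution:
    """Pair-distance distribution function P(r) from an indirect transform."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg_pr: float
    alpha: float
    chi2: float
    sigma_assumed: bool = False

    def summary(self) -> str:
        lines = [
            "Pair-distance distribution",
            "--------------------------",
            f"Dmax         {self.dmax:10.2f} A",
            f"Rg (real)    {self.rg_pr:10.3f} A",
            f"alpha        {self.alpha:10.4g}",
            f"chi2         {self.chi2:10.4g}",
            f"P(r) grid    {self.r.size} points",
        ]
        if self.sigma_assumed:
            lines.append("(no experimental sigma; 1% relative errors assumed)")
        return "\n".join(lines)

    def write(self, path) -> None:
        """Write P(r) as a 2-column TSV (r in Å, P)."""
        np.savetxt(path, np.column_stack([self.r, self.p]), delimiter="\t",
                   header="r(A)\tP(r)")


@dataclass(frozen=True)
class ProfileFit:
    """Scale + background fit of a model curve to an experimental profile."""

    scale: float
    background: float
    chi2_reduced: float
    n_points: int = 0
    sigma_assumed: bool = False

    def summary(self) -> str:
        lines = [
            "Model-to-profile fit",
            "--------------------",
            f"scale        {self.scale:10.5g}",
            f"background   {self.background:10.5g}",
            f"chi2/dof     {self.chi2_reduced:10.4g}  ({self.n_points} pts)",
        ]
        if self.sigma_assumed:
            lines.append("(no experimental sigma; 1% relative errors assumed)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_profile(path, dialect: str = "angstrom_inverse",
                 label: str | None = None) -> ScatteringProfile:
    """Read a whitespace-delimited SAXS text file (q, I[, σ]).

    Lines starting with ``#`` and lines whose leading tokens are not numeric
    (headers, beamline banners) are skipped.  Rows with non-positive ``q`` or
    non-finite intensity are dropped with a logged count.  ``dialect`` declares
    the q unit: ``angstrom_inverse`` (native) or ``nanometre_inverse``
    (q divided by 10 on read).
    """
    if dialect not in ("angstrom_inverse", "nanometre_inverse"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            try:
                values = [float(t) for t in parts[:3]]
            except ValueError:
                continue
            if len(values) < 2:
                continue
            rows.append(values)
    if len(rows) < 5:
        raise ValueError(f"{path}: fewer than 5 numeric rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    q, intensity = data[:, 0], data[:, 1]
    sigma = data[:, 2] if ncol >= 3 else None
    keep = (q > 0) & np.isfinite(q) & np.isfinite(intensity)
    if sigma is not None:
        keep &= np.isfinite(sigma) & (sigma > 0)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("%s: dropped %d invalid rows", path, dropped)
    q, intensity = q[keep], intensity[keep]
    sigma = sigma[keep] if sigma is not None else None
    if q.size < 5:
        raise ValueError(f"{path}: fewer than 5 valid rows after cleaning")
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q not strictly increasing after cleaning")
    if dialect == "nanometre_inverse":
        q = q / 10.0
    return ScatteringProfile(q, intensity, sigma,
                             label=label if label is not None else str(path))


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile in the same 3-column text dialect (q in 1/Å)."""
    sigma, assumed = profile.effective_sigma()
    cols = [profile.q, profile.intensity]
    header = f"{profile.label}\nq(1/A) I(q)"
    if not assumed:
        cols.append(sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header)


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

def _weighted_linfit(x: np.ndarray, y: np.ndarray,
                     w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least-squares line y = a + b·x; returns (b, a, R²)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = (w * (y - intercept - slope * x) ** 2).sum()
    ss_tot = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.0,
                min_points: int = 5, max_iter: int = 100) -> GuinierResult:
    """Self-consistent Guinier fit on the largest low-q window with qmax·Rg ≤ limit.

    Fits ``ln I = ln I0 − (Rg²/3)·q²`` by weighted linear least squares,
    starting from the first 20 usable points and iterating
    (fit → Rg → recompute window) to a fixed point.  A 2-cycle between adjacent
    window sizes is resolved to the smaller (more conservative) window.
    """
    usable = profile.intensity > 0
    q = profile.q[usable]
    if q.size < min_points:
        raise GuinierError("fewer than 5 points with positive intensity")
    i = profile.intensity[usable]
    sigma, assumed = profile.effective_sigma()
    sigma = sigma[usable]
    ln_i = np.log(i)
    q2 = q * q
    # σ(ln I) = σ/I  →  weights (I/σ)²
    w = (i / sigma) ** 2

    m = min(20, q.size)
    visited: set[int] = set()
    for _ in range(max_iter):
        slope, intercept, r2 = _weighted_linfit(q2[:m], ln_i[:m], w[:m])
        if slope >= 0:
            raise GuinierError("non-negative Guinier slope (no low-q decay)")
        rg = math.sqrt(-3.0 * slope)
        m_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        m_new = min(m_new, q.size)
        if m_new < min_points:
            raise GuinierError(
                f"only {m_new} points satisfy q*Rg <= {qrg_limit} (need {min_points})")
        if m_new == m:
            return GuinierResult(
                rg=rg, i0=math.exp(intercept), q_window=(float(q[0]), float(q[m - 1])),
                n_points=m, fit_r2=r2, qrg_limit=qrg_limit, sigma_assumed=assumed)
        if m_new in visited:           # 2-cycle: settle on the smaller window
            m = min(m, m_new)
            # shrink until the recomputed Rg keeps every point inside the limit
            while True:
                slope, intercept, r2 = _weighted_linfit(q2[:m], ln_i[:m], w[:m])
                if slope >= 0:
                    raise GuinierError("non-negative Guinier slope (no low-q decay)")
                rg = math.sqrt(-3.0 * slope)
                if q[m - 1] * rg <= qrg_limit + 1e-6:
                    break
                m -= 1
                if m < min_points:
                    raise GuinierError(
                        f"fewer than {min_points} points satisfy q*Rg <= {qrg_limit}")
            return GuinierResult(
                rg=rg, i0=math.exp(intercept), q_window=(float(q[0]), float(q[m - 1])),
                n_points=m, fit_r2=r2, qrg_limit=qrg_limit, sigma_assumed=assumed)
        visited.add(m)
        m = m_new
    raise GuinierError(f"Guinier window did not reach a fixed point in {max_iter} iterations")


# ---------------------------------------------------------------------------
# Indirect Fourier transform
# ---------------------------------------------------------------------------

def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with sinc(0) = 1; np.sinc is normalised to pi.
    return np.sinc(x / np.pi)


def _ift_design(q: np.ndarray, dmax: float, n_r: int):
    """Return (r grid, kernel for the interior P values).

    Discretises ``I(q) = 4π Σ_j P(r_j) sinc(q r_j) Δr`` on an ``n_r``-point r
    grid with P pinned to zero at r = 0 and r = Dmax, so only the ``n_r − 2``
    interior values are free.
    """
    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    kernel = 4.0 * np.pi * _sinc(np.outer(q, r)) * dr
    return r, kernel[:, 1:-1]


def _second_difference(n: int) -> np.ndarray:
    """Second-difference operator on the zero-padded interior vector."""
    full = np.zeros((n, n + 2))
    for j in range(n):
        full[j, j:j + 3] = (1.0, -2.0, 1.0)
    return full[:, 1:-1]


def _ift_solve(q, i_obs, sigma, dmax, alpha, n_r):
    r, a = _ift_design(q, dmax, n_r)
    aw = a / sigma[:, None]
    bw = i_obs / sigma
    d = _second_difference(n_r - 2)
    m = np.vstack([aw, math.sqrt(alpha) * d])
    y = np.concatenate([bw, np.zeros(n_r - 2)])
    p_int, _ = nnls(m, y, maxiter=30 * m.shape[1])
    chi2 = float(np.mean((aw @ p_int - bw) ** 2))
    p = np.zeros(n_r)
    p[1:-1] = p_int
    return r, p, chi2


def _auto_alpha(q, i_obs, sigma, dmax, n_r) -> float:
    """Pick the regularisation weight at the corner of the L-curve.

    Scans a wide geometric grid of α.  The residual norm traces a plateau
    (data-limited branch) that bends upward once smoothing starts to bite; the
    corner is taken as the largest α whose χ² stays within 10% of the best
    achieved, with an 0.1 absolute floor so that noise-free curves admit their
    smooth solutions.  This plateau-transition estimate of the corner is
    robust on the non-negative solution path, where pointwise curvature of
    (log ρ, log η) is numerically erratic.
    """
    _, a = _ift_design(q, dmax, n_r)
    d = _second_difference(n_r - 2)
    base = (np.linalg.norm(a / sigma[:, None]) / np.linalg.norm(d)) ** 2
    alphas = base * np.logspace(-16, 0, 17)
    eta, chi2s = [], []
    for alpha in alphas:
        _, p, chi2 = _ift_solve(q, i_obs, sigma, dmax, alpha, n_r)
        eta.append(float(np.linalg.norm(d @ p[1:-1])))
        chi2s.append(chi2)
    chi2s = np.asarray(chi2s)
    if np.all(np.asarray(eta) <= 1e-290):
        raise IFTError("auto alpha: all candidate solutions are flat; no L-curve corner")
    threshold = max(1.1 * float(chi2s.min()), 0.1)
    consistent = np.flatnonzero(chi2s <= threshold)
    return float(alphas[consistent[-1]])


def _rg_from_pr(r: np.ndarray, p: np.ndarray) -> float:
    norm = np.trapezoid(p, r)
    if norm <= 0:
        raise IFTError("indirect transform produced an all-zero P(r)")
    return math.sqrt(np.trapezoid(r * r * p, r) / (2.0 * norm))


def ift_pr(profile: ScatteringProfile, dmax="scan", alpha="auto",
           n_r: int = 101) -> PairDistribution:
    """Indirect Fourier transform of I(q) to the pair-distance distribution.

    Solves the histogram model by non-negative least squares with a Tikhonov
    penalty on second differences (weight ``alpha``); P is pinned to zero at
    both ends of the r grid.  ``dmax="scan"`` evaluates a descending geometric
    grid of candidate maximum dimensions and keeps the smallest one whose χ²
    is within 5% of the best, avoiding the monotone-χ² overestimation plateau.
    ``alpha="auto"`` uses the L-curve corner.
    """
    if len(profile) < 20:
        raise ValueError("profile must have at least 20 points")
    q, i_obs = profile.q, profile.intensity
    sigma, assumed = profile.effective_sigma()

    if dmax == "scan":
        candidates = _dmax_candidates(profile)
    else:
        dmax = float(dmax)
        if dmax <= 0:
            raise ValueError("dmax must be positive")
        candidates = np.array([dmax])

    alpha_value = (_auto_alpha(q, i_obs, sigma, float(candidates[0]), n_r)
                   if alpha == "auto" else float(alpha))

    solutions = []
    for d in candidates:
        r, p, chi2 = _ift_solve(q, i_obs, sigma, float(d), alpha_value, n_r)
        solutions.append((float(d), r, p, chi2))
    best_chi2 = min(s[3] for s in solutions)
    # smallest Dmax within 5% of the χ² minimum
    chosen = min((s for s in solutions if s[3] <= 1.05 * best_chi2),
                 key=lambda s: s[0])
    d, r, p, chi2 = chosen
    if not np.any(p > 0):
        raise IFTError("indirect transform produced an all-zero P(r)")
    return PairDistribution(r=r, p=p, dmax=d, rg_pr=_rg_from_pr(r, p),
                            alpha=alpha_value, chi2=chi2, sigma_assumed=assumed)


def _dmax_candidates(profile: ScatteringProfile, n_candidates: int = 13) -> np.ndarray:
    """Descending geometric grid of candidate Dmax values for the scan.

    The anchor estimate is 3.5·Rg from a Guinier fit (an elongated-particle
    upper scale), capped at π/q_min — the largest distance the measured q range
    can resolve; candidates run from 1.5× the estimate down to 0.4×.
    """
    cap = math.pi / profile.q[0]
    try:
        estimate = min(3.5 * guinier_fit(profile).rg, cap)
    except GuinierError:
        estimate = cap
    return np.geomspace(1.5 * estimate, 0.4 * estimate, n_candidates)


# ---------------------------------------------------------------------------
# Model-vs-data fitting
# ---------------------------------------------------------------------------

def fit_model_to_profile(model_curve: ScatteringProfile,
                         data: ScatteringProfile) -> ProfileFit:
    """Closed-form scale + background fit of a model curve to data.

    Minimises ``Σ ((c·I_model + b − I_data)/σ)²`` over (c, b) via the 2×2
    normal equations; the model is linearly interpolated onto the data grid and
    data points outside the model's q range are excluded.  χ² is reported per
    degree of freedom (N − 2).
    """
    inside = (data.q >= model_curve.q[0]) & (data.q <= model_curve.q[-1])
    if int(inside.sum()) < 3:
        raise ValueError("fewer than 3 overlapping points between model and data")
    qd = data.q[inside]
    i_d = data.intensity[inside]
    sigma_full, assumed = data.effective_sigma()
    sigma = sigma_full[inside]
    i_m = np.interp(qd, model_curve.q, model_curve.intensity)

    w = 1.0 / sigma ** 2
    s_mm = np.sum(w * i_m * i_m)
    s_m = np.sum(w * i_m)
    s_1 = np.sum(w)
    s_md = np.sum(w * i_m * i_d)
    s_d = np.sum(w * i_d)
    det = s_mm * s_1 - s_m * s_m
    if abs(det) <= 1e-12 * max(s_mm * s_1, 1e-300):
        raise ValueError("degenerate normal equations (constant model curve)")
    scale = (s_md * s_1 - s_m * s_d) / det
    background = (s_mm * s_d - s_m * s_md) / det
    if scale <= 0:
        raise ValueError("fitted scale is non-positive; model shape incompatible with data")
    resid = (scale * i_m + background - i_d) / sigma
    n = qd.size
    chi2_reduced = float(np.sum(resid ** 2) / max(n - 2, 1))
    return ProfileFit(scale=float(scale), background=float(background),
                      chi2_reduced=chi2_reduced, n_points=n, sigma_assumed=assumed)
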