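"""Fixed points, Jacobians, eigen-decompositions and gain-sweep transitions.

The structure of the reduced situated system makes its fixed points
analytic: a fixed point needs ``eta_dot = 0``, which (for P(phi) != 0)
forces ``cos(alpha) = 0``, i.e. ``alpha = +/- pi/2``.  The phi equation then
collapses to the decoupled root condition (the sensory term vanishes with
eta_dot, so the gain ``s`` drops out of the location entirely), and eta
follows from ``alpha_dot = 0``::

    eta = sin(alpha) * P(phi) / Q(phi),
    P = cos(phi) + cos(phi + c),  Q = cos(phi) - cos(phi + c)

Each decoupled root therefore spawns one candidate per alpha branch.  The
(eta, alpha) -> (-eta, -alpha) partners are *not* dynamically equivalent:
the alpha-rate is even under that reflection while eta's role flips sign,
so the four candidates carry distinct spectra.  For the canonical
parameters (a=5, b=1, c=5) the candidate at (0.11, -2.285, -pi/2) is the
attractor, (2.53, -0.435, -pi/2) the repeller, and the two mirror partners
are saddles.  Magnitudes |eta| = 2.285, 0.435 are reflection-invariant and
are what the sweep and reports compare.

Stability classes use standard Jacobian eigenvalues: all real parts
negative = attractor.  (The linearized-solution notation ``exp(-lambda*t)``
used elsewhere flips the sign convention; see the README mapping table.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root

from .model_core import (
    ETA_MIN_DEFAULT,
    HKBParams,
    VARIANT_COORDS,
    decoupled_rate,
    situated_rates,
)

__all__ = [
    "FixedPoint",
    "EigenStructure",
    "TransitionEvent",
    "EigenSweep",
    "find_decoupled_fixed_points",
    "jacobian_decoupled",
    "find_situated_fixed_points",
    "jacobian_situated",
    "jacobian_passive",
    "eigen_at",
    "sweep_eigenvalues",
    "detect_transitions",
]

_IM_TOL = 1e-9  # |Im| above this counts as a genuine complex pair
_ROOT_TOL = 1e-10


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of one system variant with its stability class."""

    location: np.ndarray
    kind: str  # attractor | repeller | saddle
    variant: str  # decoupled | situated | passive

    @property
    def phi(self) -> float:
        return float(np.atleast_1d(self.location)[0])

    @property
    def eta(self) -> float:
        return float(self.location[1])

    @property
    def alpha(self) -> float:
        return float(self.location[2])


@dataclass
class EigenStructure:
    """Sorted eigen-decomposition of a Jacobian at a fixed point.

    Eigenvalues are sorted by descending real part; ``complex_pair`` holds
    the index pair of the conjugate eigenvalues (or None), and
    ``pair_plane`` names the two dominant state coordinates of the pair's
    eigenvector (ties broken in coordinate order phi, eta, alpha, phi_star).
    """

    eigenvalues: np.ndarray
    eigenvectors: Optional[np.ndarray]  # columns match eigenvalues; None if defective
    complex_pair: Optional[tuple]
    pair_plane: Optional[str]
    defective: bool = False

    @property
    def trace(self) -> float:
        return float(np.sum(self.eigenvalues).real)

    def structure_key(self) -> tuple:
        """The discrete part of the structure: which sorted slots the pair occupies."""
        return self.complex_pair if self.complex_pair is not None else ()


@dataclass(frozen=True)
class TransitionEvent:
    """A qualitative change of the eigen-structure along the gain sweep."""

    s_value: float
    site: str  # attractor | repeller
    kind: str  # pair_vanishes | pair_appears | plane_switch


def jacobian_decoupled(phi, params: HKBParams):
    """d(phi_dot)/d(phi) of the decoupled equation: ``-a*cos(phi) - 4b*cos(2*phi)``."""
    phi = np.asarray(phi, dtype=float)
    out = -params.a * np.cos(phi) - 4.0 * params.b * np.cos(2.0 * phi)
    return out if out.ndim else float(out)


def find_decoupled_fixed_points(
    params: HKBParams, delta_omega: Optional[float] = None, n_grid: int = 4096
) -> list:
    """All roots of the decoupled rate on [0, 2*pi), classified by the 1D Jacobian.

    Dense sign scan (``n_grid`` >= 4096 points) with Brent refinement to
    1e-10.  Returns an empty list in the metastable regime.
    """
    dw = params.delta_omega0 if delta_omega is None else float(delta_omega)
    grid = np.linspace(0.0, 2.0 * np.pi, n_grid + 1)
    g = np.asarray(decoupled_rate(grid, dw, params))
    out = []
    for i in range(n_grid):
        if g[i] == 0.0:
            phi0 = grid[i]
        elif g[i] * g[i + 1] < 0:
            phi0 = brentq(
                lambda p: decoupled_rate(p, dw, params),
                grid[i],
                grid[i + 1],
                xtol=_ROOT_TOL,
            )
        else:
            continue
        if phi0 >= 2.0 * np.pi:
            continue
        j = jacobian_decoupled(phi0, params)
        kind = "attractor" if j < 0 else "repeller" if j > 0 else "saddle"
        out.append(FixedPoint(np.array([phi0]), kind, "decoupled"))
    return out


def jacobian_situated(state, params: HKBParams, eta_min: float = ETA_MIN_DEFAULT) -> np.ndarray:
    """Closed-form 3x3 Jacobian of the reduced situated system.

    The sensory term contributes ``s * d(eta_dot)/d(phi)`` and
    ``s * d(eta_dot)/d(alpha)`` to the first row; eta never enters phi_dot
    or eta_dot directly, so column 2 of rows 1-2 is zero.
    """
    x = np.asarray(state, dtype=float).reshape(3)
    phi, eta, alpha = x
    if abs(eta) <= eta_min:
        from .model_core import EtaSingularityError

        raise EtaSingularityError(eta, eta_min)
    c = params.c
    P = np.cos(phi) + np.cos(phi + c)
    dP = -np.sin(phi) - np.sin(phi + c)
    dQ = -np.sin(phi) + np.sin(phi + c)
    ca, sa = np.cos(alpha), np.sin(alpha)
    jdec = float(jacobian_decoupled(phi, params))
    return np.array(
        [
            [params.s * ca * dP + jdec, 0.0, -params.s * sa * P],
            [ca * dP, 0.0, -sa * P],
            [-sa / eta * dP + dQ, sa / eta**2 * P, -ca / eta * P],
        ]
    )


def jacobian_passive(state, params: HKBParams, eta_min: float = ETA_MIN_DEFAULT) -> np.ndarray:
    """4x4 Jacobian of the passively-coupled system.

    Block lower-triangular: phi_star never feeds back, so the phi_star
    column of the situated rows is exactly zero, and entry (4,4) is the
    decoupled Jacobian evaluated at phi_star.
    """
    x = np.asarray(state, dtype=float).reshape(4)
    J3 = jacobian_situated(x[:3], params, eta_min=eta_min)
    phi, eta, alpha, phi_star = x
    c = params.c
    dP = -np.sin(phi) - np.sin(phi + c)
    P = np.cos(phi) + np.cos(phi + c)
    ca, sa = np.cos(alpha), np.sin(alpha)
    J = np.zeros((4, 4))
    J[:3, :3] = J3
    # row 4: the copy is driven by the situated input s*eta_dot(phi, alpha)
    J[3, 0] = params.s * ca * dP
    J[3, 2] = -params.s * sa * P
    J[3, 3] = float(jacobian_decoupled(phi_star, params))
    return J


def find_situated_fixed_points(
    params: HKBParams,
    eta_min: float = ETA_MIN_DEFAULT,
    cross_validate: bool = True,
) -> list:
    """All fixed points of the reduced situated system, eigen-classified.

    Exploits the analytic structure (see module docstring); locations are
    independent of the gain ``s``.  Each closed-form candidate is
    cross-validated by a Newton solve of the full 3D system started at the
    candidate.  Candidates with a degenerate denominator Q(phi) ~ 0 are
    skipped with a warning.
    """
    roots = find_decoupled_fixed_points(params)
    out = []
    for fp1 in roots:
        phi0 = fp1.phi
        P = np.cos(phi0) + np.cos(phi0 + params.c)
        Q = np.cos(phi0) - np.cos(phi0 + params.c)
        if abs(Q) < 1e-12:
            warnings.warn(
                f"degenerate motor difference Q(phi)={Q:.2e} at phi={phi0:.4f}; "
                "candidate skipped",
                RuntimeWarning,
            )
            continue
        for sin_alpha, alpha0 in ((1.0, np.pi / 2), (-1.0, -np.pi / 2)):
            eta0 = sin_alpha * P / Q
            if abs(eta0) <= eta_min:
                warnings.warn(
                    f"candidate eta={eta0:.2e} inside the singularity guard; skipped",
                    RuntimeWarning,
                )
                continue
            loc = np.array([phi0, eta0, alpha0])
            if cross_validate:
                sol = root(
                    lambda x: situated_rates(x, params, eta_min=eta_min / 10),
                    loc,
                    method="hybr",
                    tol=1e-12,
                )
                if sol.success and np.max(np.abs(sol.x - loc)) < 1e-6:
                    loc = sol.x
            rates = situated_rates(loc, params, eta_min=eta_min / 10)
            if np.max(np.abs(rates)) > 1e-9:
                warnings.warn(
                    f"candidate at {loc} has residual rates {rates}; skipped",
                    RuntimeWarning,
                )
                continue
            ev = np.linalg.eigvals(jacobian_situated(loc, params, eta_min=eta_min / 10))
            if np.all(ev.real < 0):
                kind = "attractor"
            elif np.all(ev.real > 0):
                kind = "repeller"
            else:
                kind = "saddle"
            out.append(FixedPoint(loc, kind, "situated"))
    out.sort(key=lambda f: (f.phi, f.eta))
    return out


def _select(fps: Sequence[FixedPoint], kind: str) -> FixedPoint:
    matches = [f for f in fps if f.kind == kind]
    if not matches:
        raise ValueError(f"no fixed point of kind '{kind}' found")
    return matches[0]


def _plane_label(vec: np.ndarray, coords: Sequence[str]) -> str:
    mags = np.abs(vec)
    # two largest-magnitude coordinates; ties broken by coordinate order
    order = sorted(range(len(mags)), key=lambda i: (-mags[i], i))
    i, j = sorted(order[:2])
    return f"{coords[i]}-{coords[j]}"


def eigen_at(fp: FixedPoint, params: HKBParams, im_tol: float = _IM_TOL) -> EigenStructure:
    """Eigen-structure of the variant-appropriate Jacobian at a fixed point.

    Eigenvalues are sorted by descending real part; a conjugate pair is
    flagged when |Im| > ``im_tol``.  A defective Jacobian is flagged and
    its eigenvectors omitted.
    """
    if fp.variant == "decoupled":
        J = np.atleast_2d(jacobian_decoupled(fp.phi, params))
    elif fp.variant == "situated":
        J = jacobian_situated(fp.location, params)
    elif fp.variant == "passive":
        J = jacobian_passive(fp.location, params)
    else:
        raise ValueError(f"unknown variant {fp.variant!r}")
    w, V = np.linalg.eig(J)
    order = np.argsort(-w.real, kind="stable")
    w, V = w[order], V[:, order]
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    pair_idx = tuple(int(i) for i in np.nonzero(np.abs(w.imag) > im_tol)[0])
    complex_pair = None
    pair_plane = None
    if len(pair_idx) >= 2:
        complex_pair = pair_idx[:2]
        coords = VARIANT_COORDS[fp.variant]
        pair_plane = _plane_label(V[:, complex_pair[0]], coords)
    defective = bool(np.linalg.matrix_rank(V, tol=1e-8) < J.shape[0])
    return EigenStructure(
        eigenvalues=w,
        eigenvectors=None if defective else V,
        complex_pair=complex_pair,
        pair_plane=pair_plane,
        defective=defective,
    )


@dataclass
class EigenSweep:
    """Eigen-structures at the attractor and repeller across a gain grid.

    Fixed-point locations are computed once (they do not depend on s);
    Jacobians and spectra are re-evaluated per grid value.
    """

    params: HKBParams
    s_values: np.ndarray
    attractor: FixedPoint
    repeller: FixedPoint
    attractor_eigs: list = field(default_factory=list)
    repeller_eigs: list = field(default_factory=list)

    def site_fp(self, site: str) -> FixedPoint:
        return self.attractor if site == "attractor" else self.repeller

    def site_eigs(self, site: str) -> list:
        return self.attractor_eigs if site == "attractor" else self.repeller_eigs

    def to_frame(self):
        """Long-form table (s, site, Re/Im of lambda_1..3, pair_plane) for CSV export."""
        import pandas as pd

        rows = []
        for site in ("attractor", "repeller"):
            for s, eig in zip(self.s_values, self.site_eigs(site)):
                row = {"s": s, "site": site}
                for i, lam in enumerate(eig.eigenvalues, start=1):
                    row[f"re_lambda{i}"] = lam.real
                    row[f"im_lambda{i}"] = lam.imag
                row["pair_plane"] = eig.pair_plane or ""
                rows.append(row)
        return pd.DataFrame(rows)


def sweep_eigenvalues(params: HKBParams, s_grid) -> EigenSweep:
    """Evaluate attractor/repeller eigen-structures across a sorted gain grid."""
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing")
    fps = find_situated_fixed_points(params)
    att = _select(fps, "attractor")
    rep = _select(fps, "repeller")
    sweep = EigenSweep(params=params, s_values=s_grid, attractor=att, repeller=rep)
    for s in s_grid:
        p = params.replace(s=float(s))
        sweep.attractor_eigs.append(eigen_at(att, p))
        sweep.repeller_eigs.append(eigen_at(rep, p))
    return sweep


def _refine_transition(fp, params, s_lo, s_hi, key_lo, tol=1e-3) -> float:
    """Bisect the gain at which the discrete eigen-structure key changes."""
    while s_hi - s_lo > tol:
        mid = 0.5 * (s_lo + s_hi)
        if eigen_at(fp, params.replace(s=mid)).structure_key() == key_lo:
            s_lo = mid
        else:
            s_hi = mid
    return 0.5 * (s_lo + s_hi)


def detect_transitions(sweep: EigenSweep, tol: float = 1e-3) -> list:
    """Scan a sweep for qualitative eigen-structure changes, bisection-refined.

    Events are keyed on the conjugate pair's slot indices in the sorted
    spectrum: the pair appearing or vanishing, or a discontinuous
    reassignment of the pair between eigen-planes (``plane_switch`` - the
    real eigenvalue crossing through the pair's real part).  Smooth rotation
    of the pair's eigenvectors (a pair_plane label crossover) is not a
    transition; it is visible in the sweep table metadata.
    """
    events = []
    for site in ("attractor", "repeller"):
        fp = sweep.site_fp(site)
        eigs = sweep.site_eigs(site)
        for i in range(len(eigs) - 1):
            k0, k1 = eigs[i].structure_key(), eigs[i + 1].structure_key()
            if k0 == k1:
                continue
            if not k0 and k1:
                kind = "pair_appears"
            elif k0 and not k1:
                kind = "pair_vanishes"
            else:
                kind = "plane_switch"
            s_star = _refine_transition(
                fp, sweep.params, sweep.s_values[i], sweep.s_values[i + 1], k0, tol=tol
            )
            events.append(TransitionEvent(s_value=float(s_star), site=site, kind=kind))
    events.sort(key=lambda e: e.s_value)
    return events
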