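"""Rate equations for the three HKB system variants.

The extended HKB equation reduces two nonlinearly coupled oscillators to a
single equation for their relative phase ``phi``::

    phi_dot = delta_omega - a*sin(phi) - 2*b*sin(2*phi)

Embodied as a gradient-climbing robot controller, the frequency-difference
term becomes ``delta_omega0 + I`` with sensory input ``I = eta_dot * s``,
where ``eta`` is the stimulus level at the agent's position and ``s`` the
sensor gain.  The closed sensorimotor loop reduces to three coupled
equations in (phi, eta, alpha), with ``alpha`` the agent's orientation
relative to the gradient peak:

    phi_dot   = delta_omega0 + s*eta_dot - a*sin(phi) - 2*b*sin(2*phi)
    eta_dot   = cos(alpha) * (cos(phi) + cos(phi + c))
    alpha_dot = -sin(alpha)/eta * (cos(phi) + cos(phi + c))
                + (cos(phi) - cos(phi + c))

The passively-coupled variant appends a fourth phase ``phi_star`` that
receives the same input stream ``s*eta_dot`` but produces no motor effect.

All rate functions are pure, broadcast over numpy arrays, and never wrap
angles; wrapping is an analysis-time concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "HKBParams",
    "SituatedState",
    "PassiveState",
    "EtaSingularityError",
    "ETA_MIN_DEFAULT",
    "decoupled_rate",
    "motor_outputs",
    "sensory_input",
    "situated_rates",
    "passive_rates",
    "classify_hkb_regime",
]

#: Default guard radius around the eta = 0 singularity of the alpha rate.
ETA_MIN_DEFAULT = 1e-6

#: Coordinate names, in canonical order, per variant.
VARIANT_COORDS = {
    "decoupled": ("phi",),
    "situated": ("phi", "eta", "alpha"),
    "passive": ("phi", "eta", "alpha", "phi_star"),
}


class EtaSingularityError(ValueError):
    """Raised when the alpha rate is evaluated inside the eta guard band."""

    def __init__(self, eta: float, eta_min: float):
        self.eta = eta
        self.eta_min = eta_min
        super().__init__(
            f"alpha rate is singular at eta=0: |eta|={abs(eta):.3e} <= "
            f"eta_min={eta_min:.1e} (coordinate 'eta')"
        )


@dataclass(frozen=True)
class HKBParams:
    """Control parameters shared by the decoupled, situated and passive variants.

    Parameters
    ----------
    a, b:
        Coupling coefficients of the extended HKB equation (dimensionless,
        non-negative).  ``a/b`` fixes the mono/bi-stable regime.
    c:
        Motor bias angle in radians; breaks left/right motor symmetry.
    s:
        Sensor gain (dimensionless); the control parameter swept in the
        analysis, canonically in [0, 15].
    delta_omega0:
        Intrinsic frequency difference in rad/s.  The canonical reduced
        system uses 1; it is kept explicit so the decoupled equation stays
        general.
    """

    a: float = 5.0
    b: float = 1.0
    c: float = 5.0
    s: float = 2.5
    delta_omega0: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.s, self.delta_omega0)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"all HKB parameters must be finite, got {vals}")
        if self.a < 0 or self.b < 0:
            raise ValueError(f"coupling coefficients must be >= 0, got a={self.a}, b={self.b}")

    def replace(self, **kwargs) -> "HKBParams":
        d = asdict(self)
        d.update(kwargs)
        return HKBParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SituatedState:
    """State (phi, eta, alpha) of the situated agent."""

    phi: float
    eta: float
    alpha: float

    def to_array(self) -> np.ndarray:
        return np.array([self.phi, self.eta, self.alpha], dtype=float)

    @classmethod
    def from_array(cls, x) -> "SituatedState":
        phi, eta, alpha = np.asarray(x, dtype=float)
        return cls(phi, eta, alpha)


@dataclass
class PassiveState(SituatedState):
    """Situated state extended with the passively-coupled phase copy."""

    phi_star: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.phi, self.eta, self.alpha, self.phi_star], dtype=float)

    @classmethod
    def from_array(cls, x) -> "PassiveState":
        phi, eta, alpha, phi_star = np.asarray(x, dtype=float)
        return cls(phi, eta, alpha, phi_star)


def _check_finite(name, x):
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite value in '{name}': {x!r}")


def decoupled_rate(phi, delta_omega, params: HKBParams):
    """Rate of the decoupled extended HKB equation.

    ``phi_dot = delta_omega - a*sin(phi) - 2*b*sin(2*phi)``

    Broadcasts over array-valued ``phi``/``delta_omega``.
    """
    phi = np.asarray(phi, dtype=float)
    _check_finite("phi", phi)
    _check_finite("delta_omega", delta_omega)
    out = delta_omega - params.a * np.sin(phi) - 2.0 * params.b * np.sin(2.0 * phi)
    return out if out.ndim else float(out)


def motor_outputs(phi, c, m=1.0):
    """Right and left motor activations ``(Mr, Ml) = (m*cos(phi), m*cos(phi+c))``."""
    phi = np.asarray(phi, dtype=float)
    mr = m * np.cos(phi)
    ml = m * np.cos(phi + c)
    if phi.ndim:
        return mr, ml
    return float(mr), float(ml)


def sensory_input(eta_rate, s):
    """Sensor output ``I = eta_dot * s`` (rad/s): sensitive to stimulus change."""
    out = np.asarray(eta_rate, dtype=float) * s
    return out if out.ndim else float(out)


def _eta_terms(phi, c):
    """The motor sum P = cos(phi)+cos(phi+c) and difference Q = cos(phi)-cos(phi+c)."""
    cp = np.cos(phi)
    cpc = np.cos(phi + c)
    return cp + cpc, cp - cpc


def situated_rates(state, params: HKBParams, eta_min: float = ETA_MIN_DEFAULT):
    """Rates (phi_dot, eta_dot, alpha_dot) of the reduced situated system.

    ``state`` is array-like with last axis (phi, eta, alpha); broadcasting
    over leading axes is supported.  Raises :class:`EtaSingularityError`
    whenever any |eta| <= ``eta_min``, since the alpha rate carries a 1/eta
    factor that is genuinely singular.
    """
    x = np.asarray(state, dtype=float)
    if isinstance(state, SituatedState):
        x = state.to_array()
    _check_finite("state", x)
    phi, eta, alpha = np.moveaxis(x, -1, 0)
    if np.any(np.abs(eta) <= eta_min):
        bad = np.atleast_1d(eta)[np.argmin(np.abs(np.atleast_1d(eta)))]
        raise EtaSingularityError(float(bad), eta_min)
    P, Q = _eta_terms(phi, params.c)
    eta_dot = np.cos(alpha) * P
    phi_dot = (
        params.delta_omega0
        + eta_dot * params.s
        - params.a * np.sin(phi)
        - 2.0 * params.b * np.sin(2.0 * phi)
    )
    alpha_dot = -np.sin(alpha) / eta * P + Q
    out = np.stack(np.broadcast_arrays(phi_dot, eta_dot, alpha_dot), axis=-1)
    return out if x.ndim > 1 else out.reshape(3)


def passive_rates(state, params: HKBParams, eta_min: float = ETA_MIN_DEFAULT):
    """Rates of the 4D passively-coupled system (phi, eta, alpha, phi_star).

    The first three rates are exactly :func:`situated_rates`; the fourth is
    the HKB equation in ``phi_star`` driven by the *situated* agent's input
    stream ``s*eta_dot``.  The copy never feeds back.
    """
    x = np.asarray(state, dtype=float)
    if isinstance(state, PassiveState):
        x = state.to_array()
    _check_finite("state", x)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    trio = np.atleast_2d(situated_rates(x2[..., :3], params, eta_min=eta_min))
    phi_star = x2[..., 3]
    star_dot = (
        params.delta_omega0
        + trio[..., 1] * params.s
        - params.a * np.sin(phi_star)
        - 2.0 * params.b * np.sin(2.0 * phi_star)
    )
    out = np.concatenate([trio, star_dot[..., None]], axis=-1)
    return out.reshape(4) if squeeze else out.reshape(x.shape)


def classify_hkb_regime(delta_omega, a, b, n_grid: int = 8192) -> str:
    """Classify the decoupled phase space as monostable, bistable or metastable.

    Counts attracting roots of ``delta_omega = a*sin(phi) + 2*b*sin(2*phi)``
    on [0, 2*pi) by a dense sign scan with bisection refinement:

    * no fixed points        -> ``"metastable"`` (phase wraps; only
      attractor shadows remain),
    * exactly one attractor  -> ``"monostable"``,
    * two or more attractors -> ``"bistable"``.
    """
    if a < 0 or b < 0:
        raise ValueError("coupling coefficients must be >= 0")
    params = HKBParams(a=a, b=b, s=0.0, delta_omega0=float(delta_omega))
    # midpoint grid closed around the circle, so roots at grid nodes (e.g.
    # phi = 0 for delta_omega = 0) cannot be skipped
    grid = (np.arange(n_grid) + 0.5) * (2.0 * np.pi / n_grid)
    g = np.asarray(decoupled_rate(grid, delta_omega, params))
    gi, gj = g, np.roll(g, -1)
    down = int(np.count_nonzero((gi > 0) & (gj <= 0)))  # attracting crossings
    up = int(np.count_nonzero((gi < 0) & (gj >= 0)))
    if down + up == 0:
        return "metastable"
    if down >= 2:
        return "bistable"
    return "monostable"
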