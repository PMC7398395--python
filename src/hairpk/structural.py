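"""Structural plasma-hair pharmacokinetic model.

Three compartments: a depot (A1) absorbing drug at first-order rate k12
into a central plasma compartment (A2), which eliminates at k20 = CL/Vc;
a fraction ``frac`` of the eliminated drug is cleared into hair (A3).
Plasma concentration follows the Bateman function; the hair-scale
prediction is a ratio of the steady-state plasma trough.

Units: amounts mg, volumes L, rates 1/h, plasma concentrations mg/L.
Hair-scale predictions use an internal trough unit of HAIR_UNIT_PER_MG_L
times mg/L, which places typical predictions on the ng/mg axis of the
hair assay (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HAIR_UNIT_PER_MG_L",
    "DoseRegimen",
    "PlasmaParams",
    "HairParams",
    "CompartmentTrajectory",
    "bateman_concentration",
    "steady_state_trough",
    "integrate_system",
    "predict_hair",
]

#: Internal hair-scale trough unit per mg/L of plasma concentration.
#: 100 -> ug/dL; chosen so that frac ~ 0.16 maps the ATV steady-state
#: trough onto the observed ng/mg hair-assay scale.
HAIR_UNIT_PER_MG_L = 100.0

#: |k12 - k20| below this switches to the degenerate (equal-rate) limit.
RATE_EQUALITY_TOL = 1e-8

#: Default ODE solver tolerances.
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10


class InvalidParameterError(ValueError):
    """Raised when a kinetic parameter violates its positivity constraint."""


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: `dose_amount` mg every `interval` hours.

    ``n_doses`` is the number of doses given before the observation;
    ``None`` means steady state (an unbounded dosing history).
    """

    dose_amount: float = 300.0
    interval: float = 24.0
    n_doses: int | None = None

    def __post_init__(self) -> None:
        if self.dose_amount < 0:
            raise InvalidParameterError(f"dose_amount must be >= 0, got {self.dose_amount}")
        if self.interval <= 0:
            raise InvalidParameterError(f"interval must be > 0, got {self.interval}")
        if self.n_doses is not None and self.n_doses < 1:
            raise InvalidParameterError(f"n_doses must be >= 1, got {self.n_doses}")


@dataclass(frozen=True)
class PlasmaParams:
    """Plasma disposition parameters (apparent, oral): k12, CL/F, Vc.

    The elimination rate constant k20 = CL/Vc is always derived, never
    stored independently.
    """

    k12: float
    cl: float
    vc: float

    def __post_init__(self) -> None:
        for name in ("k12", "cl", "vc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {v}")

    @property
    def k20(self) -> float:
        return self.cl / self.vc


#: Published steady-state plasma constants for the two analytes.
ATV_PLASMA = PlasmaParams(k12=0.44, cl=10.0, vc=63.4)
RTV_PLASMA = PlasmaParams(k12=2.31, cl=12.8, vc=105.0)

ATV_DOSE = DoseRegimen(dose_amount=300.0, interval=24.0)
RTV_DOSE = DoseRegimen(dose_amount=100.0, interval=24.0)


@dataclass(frozen=True)
class HairParams:
    """Hair compartment: clearance fraction and apparent hair volume.

    ``frac`` is the hair concentration expressed as a fraction of the
    steady-state plasma trough; ``vh`` is fixed to 1 in the published
    model and only kept as an explicit scale.
    """

    frac: float = 0.16
    vh: float = 1.0

    def __post_init__(self) -> None:
        if self.frac < 0:
            raise InvalidParameterError(f"frac must be >= 0, got {self.frac}")
        if self.vh <= 0:
            raise InvalidParameterError(f"vh must be > 0, got {self.vh}")


@dataclass
class CompartmentTrajectory:
    """Integrated amounts on a time grid, plus derived concentrations."""

    t: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    c2: np.ndarray = field(init=False)
    c_hair: np.ndarray = field(init=False)
    vc: float = 1.0
    vh: float = 1.0

    def __post_init__(self) -> None:
        self.c2 = self.a2 / self.vc
        self.c_hair = self.a3 / self.vh


def _validate_plasma(p: PlasmaParams) -> None:
    # dataclass __post_init__ already enforces this for constructed objects;
    # re-check cheaply in case of duck-typed inputs.
    if p.k12 <= 0 or p.cl <= 0 or p.vc <= 0:
        raise InvalidParameterError("plasma parameters must be strictly positive")


def bateman_concentration(t, regimen: DoseRegimen, p: PlasmaParams):
    """Plasma concentration (mg/L) at time ``t`` hours after a single dose.

    The Bateman function
    ``(D/Vc) * k12/(k12-k20) * (exp(-k20 t) - exp(-k12 t))``,
    with the analytic limit ``(D/Vc) * k t exp(-k t)`` when k12 == k20.
    Accepts scalar or array ``t``.
    """
    _validate_plasma(p)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    d_over_v = regimen.dose_amount / p.vc
    k12, k20 = p.k12, p.k20
    if abs(k12 - k20) < RATE_EQUALITY_TOL:
        out = d_over_v * k12 * t * np.exp(-k12 * t)
    else:
        out = d_over_v * k12 / (k12 - k20) * (np.exp(-k20 * t) - np.exp(-k12 * t))
    return out if out.ndim else float(out)


def steady_state_trough(regimen: DoseRegimen, p: PlasmaParams) -> float:
    """Steady-state plasma trough (mg/L) at t = interval after a dose.

    Closed-form superposition of the Bateman function over an unbounded
    once-every-``interval`` dosing history:
    ``(D/Vc) * k12/(k12-k20) * [a(k20) - a(k12)]`` with
    ``a(k) = exp(-k tau)/(1 - exp(-k tau))``.
    """
    _validate_plasma(p)
    return float(
        trough_core(regimen.dose_amount, regimen.interval, p.k12, p.cl, p.vc)
    )


def trough_core(dose, tau, k12, cl, vc):
    """Vectorized steady-state trough; array-safe core used by estimation.

    All arguments broadcast. Handles the k12 ~ k20 degenerate limit
    ``(D/Vc) * k12 * tau * exp(k12 tau) / (exp(k12 tau) - 1)^2``.
    """
    k12 = np.asarray(k12, dtype=float)
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    k20 = cl / vc
    diff = k12 - k20
    degenerate = np.abs(diff) < RATE_EQUALITY_TOL
    safe_diff = np.where(degenerate, 1.0, diff)

    def accum(k):
        # exp(-k tau) / (1 - exp(-k tau)), written to avoid overflow at
        # large k*tau (-> 0) while staying exact at small k*tau
        e = np.exp(-k * tau)
        return e / (-np.expm1(-k * tau))

    regular = (dose / vc) * k12 / safe_diff * (accum(k20) - accum(k12))
    # equal-rate limit: (D/Vc) k tau exp(-k tau) / (1 - exp(-k tau))^2
    e12 = np.exp(-k12 * tau)
    limit = (dose / vc) * k12 * tau * e12 / np.square(-np.expm1(-k12 * tau))
    return np.where(degenerate, limit, regular)


def superposition_trough(regimen: DoseRegimen, p: PlasmaParams, n_doses: int) -> float:
    """Trough after ``n_doses`` doses by explicit Bateman superposition.

    Brute-force finite-history sum; converges to steady_state_trough as
    n_doses grows. Exposed mainly as a slow cross-check.
    """
    tau = regimen.interval
    times = tau * np.arange(1, n_doses + 1)  # time since each past dose
    return float(np.sum(bateman_concentration(times, regimen, p)))


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; message carries solver diagnostics."""


def integrate_system(
    regimen: DoseRegimen,
    p: PlasmaParams,
    h: HairParams,
    t_grid,
    rtol: float = ODE_RTOL,
    atol: float = ODE_ATOL,
) -> CompartmentTrajectory:
    """Numerically integrate depot -> plasma -> hair on ``t_grid`` (hours).

    Doses are instantaneous bolus additions to the depot A1 at times
    0, tau, 2*tau, ... (``regimen.n_doses`` of them; default 1 when the
    regimen requests steady state, since an unbounded history cannot be
    integrated directly).
    """
    _validate_plasma(p)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be sorted and non-negative")
    n_doses = regimen.n_doses if regimen.n_doses is not None else 1
    dose_times = regimen.interval * np.arange(n_doses)
    dose_times = dose_times[dose_times <= t_grid[-1]]

    k12, k20, frac = p.k12, p.k20, h.frac

    def rhs(_t, y):
        a1, a2, _a3 = y
        return (-k12 * a1, k12 * a1 - k20 * a2, frac * k20 * a2)

    # march piecewise over inter-dose segments, applying each dose as an
    # instantaneous bolus to A1 at the segment start
    edges = np.unique(np.concatenate([dose_times, [0.0, t_grid[-1]]]))
    a = np.empty((len(t_grid), 3))
    y0 = np.zeros(3)
    for j, edge in enumerate(edges):
        if np.any(np.isclose(edge, dose_times)):
            y0 = y0 + np.array([regimen.dose_amount, 0.0, 0.0])
        # record grid points sitting exactly on this edge (post-dose state)
        on_edge = np.isclose(t_grid, edge)
        a[on_edge] = y0
        if j + 1 >= len(edges):
            break
        seg_end = edges[j + 1]
        interior = (t_grid > edge) & (t_grid < seg_end)
        t_eval = np.unique(np.concatenate([t_grid[interior], [seg_end]]))
        sol = solve_ivp(
            rhs, (edge, seg_end), y0, t_eval=t_eval,
            rtol=rtol, atol=atol, method="LSODA",
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{edge}, {seg_end}]: {sol.message}"
            )
        for tk, yk in zip(sol.t, sol.y.T):
            hit = interior & np.isclose(t_grid, tk)
            a[hit] = yk
        y0 = sol.y[:, -1]
        # grid points exactly at seg_end are recorded on the next pass
        # (pre-dose vs post-dose: the post-dose state is what we report)
    return CompartmentTrajectory(
        t=t_grid, a1=a[:, 0], a2=a[:, 1], a3=a[:, 2], vc=p.vc, vh=h.vh
    )


def predict_hair(frac_i: float, trough: float, h: HairParams | None = None) -> float:
    """Hair-scale prediction: ``frac_i * trough / Vh``.

    ``trough`` is expected in the internal hair unit
    (HAIR_UNIT_PER_MG_L x mg/L); the result is on the ng/mg assay scale.
    """
    if frac_i < 0 or trough < 0:
        raise ValueError("frac_i and trough must be >= 0")
    vh = 1.0 if h is None else h.vh
    return frac_i * trough / vh
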