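"""Moving-mesh explicit-Euler time integration with a free boundary.

The radial grid travels with the cell velocity, which absorbs the
advection of the cell fields into node motion (total-derivative form).
The rapidly diffusing cytokine and drug fields neglect advection: they
are stepped in place and re-interpolated onto the moved grid.  Spatial
derivatives use three-point stencils valid on nonuniform spacings; the
time step obeys the explicit diffusion bound ``tau <= h^2 / (2 D)``
tightened by a safety factor, plus a cap from the fastest linear
reaction rate (the TNF-a turnover is far stiffer than any diffusion
term once the tumor has grown).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_core as mc
from .model_core import RadialMesh, TumorState
from .parameters import ParameterSet
from .treatment import ANTI_PD1, ANTI_TNF, Schedule, tvrr

__all__ = [
    "SolverError",
    "SolverSettings",
    "SimulationResult",
    "stable_timestep",
    "nonuniform_derivatives",
    "euler_step",
    "regrid",
    "simulate",
]


class SolverError(RuntimeError):
    """Integration aborted; carries a diagnostic state snapshot."""

    def __init__(self, message: str, state: TumorState | None = None,
                 mesh: RadialMesh | None = None):
        super().__init__(message)
        self.state = state
        self.mesh = mesh


@dataclass
class SolverSettings:
    """Knobs of the explicit moving-mesh integrator."""

    n_intervals: int = 100       # mesh resolution N (N+1 nodes)
    safety: float = 0.9          # CFL safety factor
    regrid_ratio: float = 1.5    # max/min spacing ratio triggering a regrid
    regrid_growth: float = 0.1   # boundary growth fraction triggering a regrid
    conservation_tol: float = 0.01  # allowed |D+T+C-rho_tot|, fraction of rho_tot
    t_end: float | None = 30.0   # None: take the schedule's end time
    output_every: float = 0.5    # recording cadence (days)
    renormalize: bool = False    # project (D,T,C) back onto the constraint

    def __post_init__(self) -> None:
        if self.n_intervals < 8:
            raise ValueError("need at least 8 mesh intervals")
        if not (0 < self.safety <= 1):
            raise ValueError("safety factor must lie in (0, 1]")
        if self.regrid_ratio <= 1:
            raise ValueError("regrid ratio must exceed 1")
        if self.conservation_tol <= 0 or self.output_every <= 0:
            raise ValueError("tolerances and cadence must be positive")


def stable_timestep(mesh: RadialMesh,
                    params: ParameterSet,
                    settings: SolverSettings) -> float:
    """Diffusion-stability bound ``safety * min(h)^2 / (2 D_max)`` (days)."""
    h_min = mesh.spacings.min()
    if h_min <= 0:
        raise SolverError("degenerate mesh: zero or negative spacing")
    return settings.safety * h_min * h_min / (2.0 * params.delta_max)


def _reaction_rate_cap(state: TumorState, params: ParameterSet) -> float:
    """Fastest linear decay rate present in the reaction terms (1/day)."""
    p = params
    return max(
        p.d_Talpha + p.mu_TalphaB * float(state.B.max(initial=0.0)),
        p.d_B + p.mu_TalphaB * float(state.Ta.max(initial=0.0)),
        p.d_A + p.mu_PA * float(state.P.max(initial=0.0)),
        p.d_I12,
        p.d_T,
        p.d_D,
        p.d_C + p.lambda_C + p.eta * float(state.T.max(initial=0.0)),
    )


def nonuniform_derivatives(x_minus, x_center, x_plus, h1, hm1):
    """First and second derivatives from a three-point nonuniform stencil.

    ``h1 = r[i+1] - r[i] > 0`` and ``hm1 = r[i-1] - r[i] < 0``.  On a
    uniform mesh the formulas reduce to the usual central differences;
    they are exact for quadratics on any mesh.
    """
    h1 = np.asarray(h1, dtype=float)
    hm1 = np.asarray(hm1, dtype=float)
    if np.any(h1 <= 0) or np.any(hm1 >= 0):
        raise ValueError("need h1 > 0 and hm1 < 0")
    # exact for quadratics on any mesh; reduce to central differences when
    # hm1 = -h1
    first = (hm1 ** 2 * x_plus - h1 ** 2 * x_minus
             + (h1 ** 2 - hm1 ** 2) * x_center) / (h1 * hm1 * (hm1 - h1))
    second = 2.0 * (hm1 * x_plus - h1 * x_minus + (h1 - hm1) * x_center) \
        / (h1 * (h1 * hm1 - hm1 ** 2))
    return first, second


def _interior_laplacian(X: np.ndarray, r: np.ndarray):
    """Radial Laplacian X_rr + (2/r) X_r at interior nodes of stacked rows."""
    h1 = r[2:] - r[1:-1]
    hm1 = r[:-2] - r[1:-1]
    first, second = nonuniform_derivatives(
        X[:, :-2], X[:, 1:-1], X[:, 2:], h1, hm1)
    return second + (2.0 / r[1:-1]) * first


_CELL_ROWS = np.array([mc.FIELD_NAMES.index(n) for n in mc.CELL_FIELDS])
_FLUID_ROWS = np.array([mc.FIELD_NAMES.index(n) for n in mc.FLUID_FIELDS])


def _diffusivities(params: ParameterSet) -> np.ndarray:
    return np.array([params.delta_D, params.delta_T, params.delta_C,
                     params.delta_I12, params.delta_Talpha, params.delta_T,
                     params.delta_A, params.delta_B])
    # order: D T C I12 Ta P A B; P diffuses with the T cells that carry it


def euler_step(state: TumorState,
               mesh: RadialMesh,
               reactions: dict[str, np.ndarray],
               u: np.ndarray,
               tau: float,
               params: ParameterSet,
               div_u: np.ndarray | None = None,
               ) -> tuple[TumorState, RadialMesh, int]:
    """One explicit Euler step; returns (state', mesh', clip count).

    Cell fields (and membrane-bound PD-1) follow the moving nodes and
    pick up the ``-X div(u)`` compression term.  By default ``div(u)``
    comes from the velocity closure identity ``div(u) = S / rho_tot``
    (exact, and it preserves the discrete cell-density constraint);
    callers testing transport-free dynamics may pass it explicitly.
    Cytokines and drugs are stepped in place and re-interpolated to the
    new node positions.
    """
    r = mesh.r
    X = state.stack()
    F = np.stack([reactions[name] for name in mc.FIELD_NAMES])
    delta = _diffusivities(params)[:, None]

    if div_u is None:
        S = reactions["D"] + reactions["T"] + reactions["C"]
        div_u = S / params.rho_tot

    lap = np.zeros_like(X)
    lap[:, 1:-1] = _interior_laplacian(X, r)
    # boundary node is set by the boundary conditions; center node below

    X_new = X + tau * (delta * lap + F)
    X_new[_CELL_ROWS] -= tau * X[_CELL_ROWS] * div_u

    # r = 0 symmetry node: Laplacian limit is 3 X_rr = 6 (X_1 - X_0) / r_1^2,
    # whose explicit bound (h^2 / 6D) is three times stricter than the global
    # step bound, so its diffusion exchange is taken semi-implicitly.
    a0 = 6.0 * delta[:, 0] * tau / (r[1] * r[1])
    rhs0 = X[:, 0] + a0 * X[:, 1] + tau * F[:, 0]
    rhs0[_CELL_ROWS] -= tau * X[_CELL_ROWS, 0] * div_u[0]
    X_new[:, 0] = rhs0 / (1.0 + a0)

    r_new = r + u * tau
    if r_new[-1] <= 0 or np.any(np.diff(r_new) <= 0):
        raise SolverError("mesh folded over during node motion", state, mesh)

    # fluid fields were updated at the old node positions
    for i in _FLUID_ROWS:
        X_new[i] = np.interp(r_new, r, X_new[i])

    if not np.all(np.isfinite(X_new)):
        raise SolverError("non-finite field values after step", state, mesh)

    neg = X_new < 0
    clip_count = int(np.count_nonzero(neg))
    if clip_count:
        euler_step.last_clips = {
            name: int(np.count_nonzero(neg[i]))
            for i, name in enumerate(mc.FIELD_NAMES) if neg[i].any()}
        np.maximum(X_new, 0.0, out=X_new)

    t_new = mesh.t + tau
    new_state = TumorState.from_stack(X_new, t=t_new)
    new_mesh = RadialMesh(r_new, t=t_new)
    mc.apply_boundary_conditions(new_state, new_mesh, params)
    return new_state, new_mesh, clip_count


def regrid(state: TumorState,
           mesh: RadialMesh,
           n_intervals: int) -> tuple[TumorState, RadialMesh]:
    """Interpolate every field onto a fresh uniform mesh over [0, R]."""
    new_mesh = RadialMesh.uniform(mesh.R, n_intervals, t=mesh.t)
    fields = {name: np.interp(new_mesh.r, mesh.r, getattr(state, name))
              for name in mc.FIELD_NAMES}
    return TumorState(**fields, t=state.t), new_mesh


def _volume_average(x: np.ndarray, r: np.ndarray) -> float:
    R = r[-1]
    return float(3.0 / R ** 3 * np.trapezoid(x * r * r, r))


@dataclass
class SimulationResult:
    """Time series of volume-averaged fields plus run diagnostics."""

    times: np.ndarray
    averages: dict[str, np.ndarray]
    radius: np.ndarray
    volume: np.ndarray
    conservation_dev: np.ndarray  # max |D+T+C-rho_tot| per output time
    clip_count: int
    n_steps: int
    regrid_count: int
    params: ParameterSet
    schedule: Schedule
    settings: SolverSettings
    final_state: TumorState | None = None
    final_mesh: RadialMesh | None = None

    @property
    def tvrr(self) -> float:
        """Volume reduction (%) over the simulated course."""
        return tvrr(float(self.volume[0]), float(self.volume[-1]))

    @property
    def max_conservation_dev(self) -> float:
        return float(self.conservation_dev.max())

    def average(self, name: str) -> np.ndarray:
        return self.averages[name]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "radius": self.radius, "volume": self.volume,
                "conservation_dev": self.conservation_dev}
        for name in mc.FIELD_NAMES:
            data[f"avg_{name}"] = self.averages[name]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def scalars(self) -> dict:
        return {
            "tvrr_percent": self.tvrr,
            "final_radius_cm": float(self.radius[-1]),
            "final_volume_cm3": float(self.volume[-1]),
            "max_conservation_dev": self.max_conservation_dev,
            "clip_count": self.clip_count,
            "n_steps": self.n_steps,
            "regrid_count": self.regrid_count,
        }

    def scalars_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.scalars(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def simulate(params: ParameterSet,
             schedule: Schedule | None = None,
             R0: float = 0.5,
             settings: SolverSettings | None = None,
             keep_final_state: bool = False) -> SimulationResult:
    """Integrate the model from the standard initial state.

    ``schedule=None`` runs the no-drug control.  The run ends at
    ``settings.t_end`` (or the schedule's end time when that is None).
    The inner loop is the jitted kernel in :mod:`tumortx._kernel`, which
    replicates :func:`euler_step`; diagnostics (conservation, optional
    renormalization) are evaluated at the output cadence.  Aborts with
    :class:`SolverError` on instability or when the cell density
    constraint drifts beyond the configured tolerance.
    """
    from . import _kernel

    settings = settings or SolverSettings()
    t_end = settings.t_end
    if t_end is None:
        if schedule is None:
            raise ValueError("need either settings.t_end or a schedule")
        t_end = schedule.t_end
    schedule = schedule or Schedule.control(t_end=t_end)

    state, mesh = mc.initial_state(R0, params, settings.n_intervals)
    tol = settings.conservation_tol * params.rho_tot

    pv = _kernel.pack_params(params)
    days_a = np.asarray(schedule.days(ANTI_PD1), dtype=float)
    gammas_a = np.asarray(schedule.amplitudes(ANTI_PD1), dtype=float)
    days_b = np.asarray(schedule.days(ANTI_TNF), dtype=float)
    gammas_b = np.asarray(schedule.amplitudes(ANTI_TNF), dtype=float)

    X = np.ascontiguousarray(state.stack())
    r = mesh.r.copy()
    t = 0.0

    out_times: list[float] = []
    out_avgs: dict[str, list[float]] = {name: [] for name in mc.FIELD_NAMES}
    out_radius: list[float] = []
    out_dev: list[float] = []

    def record():
        out_times.append(t)
        for i, name in enumerate(mc.FIELD_NAMES):
            out_avgs[name].append(_volume_average(X[i], r))
        out_radius.append(float(r[-1]))
        cell_sum = X[0] + X[1] + X[2]
        out_dev.append(float(np.abs(cell_sum - params.rho_tot).max()))

    record()
    R_last_regrid = float(r[-1])
    clip_total = 0
    n_steps = 0
    regrid_count = 0

    n_outputs = max(1, int(round(t_end / settings.output_every)))
    outputs = np.minimum(settings.output_every * np.arange(1, n_outputs + 1),
                         t_end)
    if outputs[-1] < t_end - 1e-12:
        outputs = np.append(outputs, t_end)

    for t_stop in outputs:
        t, steps, clips, regrids, R_last_regrid, status = _kernel.advance(
            X, r, t, float(t_stop), pv, days_a, gammas_a, days_b, gammas_b,
            settings.safety, settings.regrid_ratio, settings.regrid_growth,
            R_last_regrid)
        n_steps += steps
        clip_total += clips
        regrid_count += regrids
        if status != 0:
            bad_state = mc.TumorState.from_stack(X, t=t)
            msg = ("non-finite field values" if status == 1
                   else "mesh folded over during node motion")
            raise SolverError(f"{msg} at t={t:.4f}", bad_state)

        if settings.renormalize:
            scale = params.rho_tot / (X[0] + X[1] + X[2])
            X[0] *= scale
            X[1] *= scale
            X[2] *= scale

        record()
        if out_dev[-1] > tol:
            raise SolverError(
                f"cell density constraint violated at t={t:.3f}: "
                f"deviation {out_dev[-1]:.3g} exceeds tolerance {tol:.3g}",
                mc.TumorState.from_stack(X, t=t))

    state = mc.TumorState.from_stack(X, t=t)
    mesh = RadialMesh(r, t=t)
    radius = np.array(out_radius)
    return SimulationResult(
        times=np.array(out_times),
        averages={k: np.array(v) for k, v in out_avgs.items()},
        radius=radius,
        volume=4.0 / 3.0 * np.pi * radius ** 3,
        conservation_dev=np.array(out_dev),
        clip_count=clip_total,
        n_steps=n_steps,
        regrid_count=regrid_count,
        params=params,
        schedule=schedule,
        settings=settings,
        final_state=state.copy() if keep_final_state else None,
        final_mesh=RadialMesh(mesh.r.copy(), t=mesh.t) if keep_final_state else None,
    )
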