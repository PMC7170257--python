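"""In-silico experiments: control growth, dose-grid efficacy maps, and
global sensitivity analysis (Latin hypercube sampling + partial rank
correlation against the day-30 tumor radius)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import FIELD_NAMES
from .parameters import ParameterSet
from .solver import SimulationResult, SolverSettings, simulate
from .treatment import Schedule, build_human_schedule, build_mouse_schedule, tvrr

__all__ = [
    "run_control",
    "EfficacyMap",
    "efficacy_map",
    "lhs_sample",
    "prcc",
    "SensitivityResult",
    "run_sensitivity",
    "SENSITIVITY_PARAMS",
    "fig3a_schedule",
]

#: parameters screened by the sensitivity analysis: the production rates
#: of the five dynamic equations, the two drug blocking rates, and the
#: T-cell kill rate.
SENSITIVITY_PARAMS = (
    "lambda_DC_D0",
    "lambda_TI12_T0",
    "lambda_C_mouse",
    "lambda_I12D",
    "lambda_TalphaT",
    "A_Talpha",
    "mu_TalphaB",
    "mu_PA",
    "eta",
)


def fig3a_schedule(gamma_A: float = 1.0e-10,
                   gamma_B: float = 1.0e-6,
                   t_end: float = 30.0) -> Schedule:
    """Mouse protocol with both drugs injected at days 6, 10 and 13."""
    return build_mouse_schedule([6, 10, 13], gamma_A, gamma_B, t_end=t_end)


def run_control(params: ParameterSet | None = None,
                R0: float = 0.5,
                days: float = 30.0,
                settings: SolverSettings | None = None,
                check_plateau: bool = True) -> SimulationResult:
    """No-drug run; optionally checks that averaged fields plateau.

    The plateau check requires every nonvanishing averaged field to
    change by less than 20% over the final five days (the tumor volume
    keeps growing and is exempt).
    """
    params = params or ParameterSet()
    settings = settings or SolverSettings()
    settings = dataclasses.replace(settings, t_end=float(days))
    result = simulate(params, schedule=None, R0=R0, settings=settings)

    if check_plateau and days > 5.0:
        i_ref = int(np.searchsorted(result.times, days - 5.0))
        for name in FIELD_NAMES:
            series = result.averages[name]
            ref = series[i_ref]
            if abs(ref) < 1e-30:  # drug-free fields stay at zero
                continue
            change = abs(series[-1] - ref) / abs(ref)
            if change > 0.20:
                raise RuntimeError(
                    f"averaged {name} has not plateaued: {change:.1%} change "
                    "over the final 5 days")
    return result


@dataclass
class EfficacyMap:
    """TVRR (%) on a (gamma_A, gamma_B) dose grid for one schedule."""

    variant: str
    R0: float
    n_cycles: int
    gamma_A_grid: np.ndarray
    gamma_B_grid: np.ndarray
    tvrr_matrix: np.ndarray  # shape (len(gamma_A_grid), len(gamma_B_grid))

    def __post_init__(self) -> None:
        self.gamma_A_grid = np.asarray(self.gamma_A_grid, dtype=float)
        self.gamma_B_grid = np.asarray(self.gamma_B_grid, dtype=float)
        self.tvrr_matrix = np.asarray(self.tvrr_matrix, dtype=float)
        expected = (self.gamma_A_grid.size, self.gamma_B_grid.size)
        if self.tvrr_matrix.shape != expected:
            raise ValueError(
                f"matrix shape {self.tvrr_matrix.shape} != grids {expected}")
        if np.any(self.tvrr_matrix > 100.0 + 1e-9):
            raise ValueError("TVRR cannot exceed 100%")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tvrr_matrix,
                            index=pd.Index(self.gamma_A_grid, name="gamma_A"),
                            columns=pd.Index(self.gamma_B_grid, name="gamma_B"))

    def to_csv(self, path: str | Path) -> None:
        """Tidy long format: one (gamma_A, gamma_B, tvrr_percent) row."""
        long = (self.to_frame().stack().rename("tvrr_percent")
                .reset_index())
        long.insert(0, "variant", self.variant)
        long.to_csv(path, index=False)


def efficacy_map(variant: str,
                 R0: float,
                 n_cycles: int,
                 gamma_A_grid: Sequence[float],
                 gamma_B_grid: Sequence[float],
                 params: ParameterSet | None = None,
                 settings: SolverSettings | None = None) -> EfficacyMap:
    """One treatment simulation per dose pair; human parameters.

    The run length is the full treatment course (21-day cycles).
    """
    gamma_A_grid = np.asarray(list(gamma_A_grid), dtype=float)
    gamma_B_grid = np.asarray(list(gamma_B_grid), dtype=float)
    if gamma_A_grid.size == 0 or gamma_B_grid.size == 0:
        raise ValueError("dose grids must be nonempty")
    params = params or ParameterSet(species="human")
    settings = settings or SolverSettings()

    matrix = np.empty((gamma_A_grid.size, gamma_B_grid.size))
    for i, gA in enumerate(gamma_A_grid):
        for j, gB in enumerate(gamma_B_grid):
            schedule = build_human_schedule(variant, n_cycles, gA, gB)
            run_settings = dataclasses.replace(settings, t_end=schedule.t_end)
            result = simulate(params, schedule, R0=R0, settings=run_settings)
            matrix[i, j] = result.tvrr
    return EfficacyMap(variant=variant, R0=R0, n_cycles=n_cycles,
                       gamma_A_grid=gamma_A_grid, gamma_B_grid=gamma_B_grid,
                       tvrr_matrix=matrix)


def lhs_sample(ranges: Sequence[tuple[float, float]],
               n: int,
               seed: int) -> np.ndarray:
    """Latin hypercube sample: one point per stratum in every dimension.

    Each column is a random permutation of the ``n`` equiprobable strata
    with a uniform jitter inside each stratum, scaled to its range.
    Fully determined by ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    p = len(ranges)
    out = np.empty((n, p))
    for j, (low, high) in enumerate(ranges):
        if not (low < high):
            raise ValueError(f"invalid range for dimension {j}: ({low}, {high})")
        strata = (rng.permutation(n) + rng.uniform(size=n)) / n
        out[:, j] = low + strata * (high - low)
    return out


@dataclass
class SensitivityResult:
    """PRCC of each screened parameter against a scalar model output."""

    names: tuple[str, ...]
    ranges: tuple[tuple[float, float], ...]
    n: int
    seed: int | None
    prcc: np.ndarray
    p_values: np.ndarray
    output_name: str = "tumor radius at day 30"
    flagged: tuple[str, ...] = ()  # constant columns with undefined PRCC

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.names),
            "low": [r[0] for r in self.ranges],
            "high": [r[1] for r in self.ranges],
            "prcc": self.prcc,
            "p_value": self.p_values,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def prcc(samples: np.ndarray,
         outputs: np.ndarray,
         names: Sequence[str] | None = None,
         ranges: Sequence[tuple[float, float]] | None = None,
         seed: int | None = None) -> SensitivityResult:
    """Partial rank correlation of each input column with the output.

    All columns are rank-transformed; for parameter ``j`` the linear
    effect of every other parameter is regressed out of both the
    parameter ranks and the output ranks, and the PRCC is the Pearson
    correlation of the two residual vectors.  The p-value comes from the
    t statistic with ``n - 2 - (p - 1)`` degrees of freedom.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(outputs, dtype=float)
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("outputs must be a length-n vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("outputs must be finite")
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 samples, got n={n}, p={p}")

    names = tuple(names) if names is not None else tuple(
        f"x{j}" for j in range(p))
    if ranges is None:
        ranges = tuple((float(X[:, j].min()), float(X[:, j].max()))
                       for j in range(p))

    Xr = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    yr = stats.rankdata(y)

    flagged = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0.0]

    prcc_vals = np.full(p, np.nan)
    p_vals = np.full(p, np.nan)
    dof = n - 2 - (p - 1)
    for j in range(p):
        if names[j] in flagged:
            continue
        others = np.delete(Xr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        bx, *_ = np.linalg.lstsq(design, Xr[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(design, yr, rcond=None)
        rx = Xr[:, j] - design @ bx
        ry = yr - design @ by
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        if denom == 0.0:
            flagged.append(names[j])
            continue
        rho = float(np.dot(rx, ry) / denom)
        rho = max(-1.0, min(1.0, rho))
        prcc_vals[j] = rho
        if abs(rho) >= 1.0:
            p_vals[j] = 0.0
        else:
            t_stat = rho * np.sqrt(dof / (1.0 - rho * rho))
            p_vals[j] = 2.0 * stats.t.sf(abs(t_stat), dof)

    return SensitivityResult(names=names, ranges=tuple(ranges), n=n, seed=seed,
                             prcc=prcc_vals, p_values=p_vals,
                             flagged=tuple(flagged))


def run_sensitivity(params: ParameterSet | None = None,
                    n: int = 200,
                    seed: int = 0,
                    rel_range: float = 0.5,
                    param_names: Sequence[str] = SENSITIVITY_PARAMS,
                    schedule: Schedule | None = None,
                    R0: float = 0.5,
                    days: float = 30.0,
                    settings: SolverSettings | None = None,
                    ) -> SensitivityResult:
    """LHS/PRCC screen of the production and blocking rates.

    Ranges default to +/- ``rel_range`` around the baseline value of each
    parameter.  Runs use the mouse parameter set; a treatment schedule
    (default: the day-6/10/13 mouse protocol) keeps both drug blocking
    rates active.  The output is the tumor radius at the end of the run.
    """
    params = params or ParameterSet()
    settings = settings or SolverSettings()
    settings = dataclasses.replace(settings, t_end=None)
    if schedule is None:
        inject = [d for d in (6, 10, 13) if d < days]
        schedule = (build_mouse_schedule(inject, 1.0e-10, 1.0e-6, t_end=days)
                    if inject else Schedule.control(t_end=days))

    baseline = params.to_dict()
    ranges = tuple(
        (baseline[name] * (1.0 - rel_range), baseline[name] * (1.0 + rel_range))
        for name in param_names)
    samples = lhs_sample(ranges, n, seed)

    outputs = np.empty(n)
    for i in range(n):
        overrides = {name: float(samples[i, j])
                     for j, name in enumerate(param_names)}
        # sampled mouse growth may dip below the (unused) human rate;
        # keep the species ordering invariant satisfied
        if "lambda_C_mouse" in overrides:
            overrides["lambda_C_human"] = min(params.lambda_C_human,
                                              overrides["lambda_C_mouse"])
        run_params = params.with_overrides(**overrides)
        result = simulate(run_params, schedule, R0=R0, settings=settings)
        outputs[i] = result.radius[-1]

    return prcc(samples, outputs, names=param_names, ranges=ranges, seed=seed)
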