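"""Spatial state, algebraic relations and reaction terms of the model.

The tumor is a radially symmetric sphere of radius ``R(t)`` filled with
three cell populations (dendritic cells D, cytotoxic lymphocytes T,
cancer cells C) whose total density is constant, two cytokines (IL-12,
TNF-a), the checkpoint receptor PD-1 (P) and two drugs (anti-PD-1 A,
anti-TNF-a B).  The ligands PD-L1, TIM-3 and Gal-9 and the two
receptor-ligand complexes are algebraic (quasi-steady) functions of the
evolved fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "FIELD_NAMES",
    "CELL_FIELDS",
    "FLUID_FIELDS",
    "RadialMesh",
    "TumorState",
    "DerivedFields",
    "derived_fields",
    "reaction_terms",
    "velocity_field",
    "apply_boundary_conditions",
    "initial_state",
]

#: evolved fields, in a fixed order used throughout the solver
FIELD_NAMES = ("D", "T", "C", "I12", "Ta", "P", "A", "B")
#: fields advected with the cell velocity (cells plus membrane-bound PD-1)
CELL_FIELDS = ("D", "T", "C", "P")
#: rapidly diffusing fields whose advection is neglected
FLUID_FIELDS = ("I12", "Ta", "A", "B")

#: guard for the P/T ratio when T underflows (g/cm^3)
EPS_T = 1.0e-12


@dataclass
class RadialMesh:
    """Ordered radial nodes on [0, R(t)]."""

    r: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1 or self.r.size < 2:
            raise ValueError("mesh needs at least two nodes")
        if self.r[0] != 0.0:
            raise ValueError("innermost node must sit at r = 0")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("node positions must be strictly increasing")

    @property
    def R(self) -> float:
        """Free-boundary radius (cm)."""
        return float(self.r[-1])

    @property
    def n_nodes(self) -> int:
        return self.r.size

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.r)

    @classmethod
    def uniform(cls, R: float, n_intervals: int, t: float = 0.0) -> "RadialMesh":
        if R <= 0:
            raise ValueError(f"radius must be positive, got {R}")
        return cls(np.linspace(0.0, R, n_intervals + 1), t=t)


@dataclass
class TumorState:
    """Per-node values of the eight evolved fields at one time point."""

    D: np.ndarray
    T: np.ndarray
    C: np.ndarray
    I12: np.ndarray
    Ta: np.ndarray
    P: np.ndarray
    A: np.ndarray
    B: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in FIELD_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        sizes = {getattr(self, name).size for name in FIELD_NAMES}
        if len(sizes) != 1:
            raise ValueError("all fields must share one mesh")

    def stack(self) -> np.ndarray:
        """Fields as one (8, n_nodes) array in FIELD_NAMES order."""
        return np.stack([getattr(self, name) for name in FIELD_NAMES])

    @classmethod
    def from_stack(cls, X: np.ndarray, t: float) -> "TumorState":
        return cls(*(X[i] for i in range(len(FIELD_NAMES))), t=t)

    def copy(self) -> "TumorState":
        return TumorState(*(getattr(self, n).copy() for n in FIELD_NAMES),
                          t=self.t)

    def cell_sum(self) -> np.ndarray:
        return self.D + self.T + self.C

    def validate(self, params: ParameterSet, tol: float = 0.01) -> None:
        for name in FIELD_NAMES:
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"field {name} has negative entries")
        dev = np.abs(self.cell_sum() - params.rho_tot).max()
        if dev > tol * params.rho_tot:
            raise ValueError(
                f"cell density constraint violated by {dev:.3g} g/cm^3")


@dataclass
class DerivedFields:
    """Quasi-steady ligand fields, inhibition factors and velocity."""

    L: np.ndarray        # PD-L1, g/cm^3
    TM: np.ndarray       # TIM-3, g/cm^3
    G: np.ndarray        # Gal-9, g/cm^3
    f_Q1: np.ndarray     # PD-1:PD-L1 inhibition factor, in (0, 1]
    f_Q2: np.ndarray     # TIM-3:Gal-9 inhibition factor, in (0, 1]
    u: np.ndarray | None = None  # radial cell velocity, cm/day
    PL: np.ndarray | None = None   # complex-forming product P*L, g^2/cm^6
    TMG: np.ndarray | None = None  # complex-forming product TM*G, g^2/cm^6


def derived_fields(state: TumorState, params: ParameterSet) -> DerivedFields:
    """Evaluate the algebraic ligand/checkpoint relations.

    PD-L1 sits on T cells and (at reduced expression eps_C) on cancer
    cells and is upregulated by TNF-a; TIM-3 sits on T cells, upregulated
    by TNF-a and further by the anti-PD-1 drug; Gal-9 is proportional to
    the cancer-cell density.  The two complexes are quasi-steady, so the
    inhibition factors depend on the products P*L and TM*G only.
    """
    p = params
    ta_sat = state.Ta / (p.K_Talpha + state.Ta)
    a_sat = state.A / (p.K_A + state.A)

    L = p.rho_L * (state.T + p.eps_C * state.C) * (1.0 + p.alpha_L * ta_sat)
    TM = p.rho_M * state.T * (1.0 + p.alpha_T * ta_sat * (1.0 + p.alpha_MA * a_sat))
    G = p.rho_G * state.C

    PL = state.P * L
    TMG = TM * G
    f_Q1 = 1.0 / (1.0 + PL / p.K_TQ1)
    f_Q2 = 1.0 / (1.0 + TMG / p.K_TQ2)
    return DerivedFields(L=L, TM=TM, G=G, f_Q1=f_Q1, f_Q2=f_Q2,
                         PL=PL, TMG=TMG)


def reaction_terms(state: TumorState,
                   derived: DerivedFields,
                   dose_rates: tuple[float, float],
                   params: ParameterSet) -> dict[str, np.ndarray]:
    """Transport-free right-hand sides of all eight fields (g/cm^3/day).

    ``dose_rates`` is the pair of instantaneous volumetric drug source
    rates (gamma_A(t), gamma_B(t)).
    """
    p = params
    gA, gB = dose_rates

    F_D = p.lambda_DC_D0 * state.C / (p.K_C + state.C) - p.d_D * state.D
    F_T = (p.lambda_TI12_T0 * state.I12 / (p.K_I12 + state.I12)
           * derived.f_Q1 * derived.f_Q2
           - p.d_T * state.T)
    F_C = (p.lambda_C * state.C * (1.0 - state.C / p.C_M)
           - p.eta * state.T * state.C
           - p.d_C * state.C)
    F_I12 = p.lambda_I12D * state.D - p.d_I12 * state.I12
    F_Ta = (p.A_Talpha + p.lambda_TalphaT * state.T
            - p.mu_TalphaB * state.Ta * state.B
            - p.d_Talpha * state.Ta)
    # P tracks T multiplicatively (P = rho_P*T is exact without drug);
    # the ratio is guarded against T underflow only.
    ratio = state.P / np.maximum(state.T, EPS_T)
    F_P = ratio * F_T - p.mu_PA * state.P * state.A
    F_A = gA - p.mu_PA * state.P * state.A - p.d_A * state.A
    F_B = gB - p.mu_TalphaB * state.Ta * state.B - p.d_B * state.B

    return {"D": F_D, "T": F_T, "C": F_C, "I12": F_I12,
            "Ta": F_Ta, "P": F_P, "A": F_A, "B": F_B}


def velocity_field(source_sum: np.ndarray,
                   mesh: RadialMesh,
                   params: ParameterSet) -> np.ndarray:
    """Radial cell velocity from the incompressibility closure (cm/day).

    Solves ``(1/r^2) d(r^2 u)/dr = S / rho_tot`` with ``u(0) = 0`` by
    cumulative trapezoidal quadrature, where ``S = F_D + F_T + F_C`` is
    the summed cell reaction rate.  Diffusion contributions cancel
    because the cells share one diffusivity and a constant total density.
    """
    r = mesh.r
    S = np.asarray(source_sum, dtype=float)
    if S.shape != r.shape:
        raise ValueError("source and mesh sizes differ")
    # integrate r^2 * S exactly for piecewise-linear S (plain trapezoid on
    # r^2*S has O(1) relative error on the first interval, where u ~ r)
    a, b = r[:-1], r[1:]
    Sa, Sb = S[:-1], S[1:]
    slope = (Sb - Sa) / (b - a)
    cubes = (b ** 3 - a ** 3) / 3.0
    seg = Sa * cubes + slope * ((b ** 4 - a ** 4) / 4.0 - a * cubes)
    flux = np.concatenate(([0.0], np.cumsum(seg))) / params.rho_tot
    u = np.empty_like(r)
    u[0] = 0.0
    u[1:] = flux[1:] / (r[1:] * r[1:])
    return u


def boundary_flux_rate(I12_boundary: float, params: ParameterSet) -> float:
    """T-cell influx coefficient sigma_T(I12) at the rim (1/cm)."""
    return params.sigma_0 * I12_boundary / (params.K_I12 + I12_boundary)


def apply_boundary_conditions(state: TumorState,
                              mesh: RadialMesh,
                              params: ParameterSet) -> TumorState:
    """Impose the rim conditions on the outermost node (in place).

    Robin influx for T and P (inactive lymphocytes at density T_hat cross
    the boundary, carrying PD-1 at ratio rho_P), homogeneous Neumann for
    D, I12, TNF-a and both drugs, and the cancer density closed by the
    constant-total-density constraint.  The center node needs no
    condition here: symmetry is built into the r = 0 stencil.
    """
    h = mesh.r[-1] - mesh.r[-2]
    sigma = boundary_flux_rate(float(state.I12[-1]), params)
    # first-order one-sided discretization of  X' + sigma (X - Xhat) = 0
    state.T[-1] = (state.T[-2] + h * sigma * params.T_hat) / (1.0 + h * sigma)
    state.P[-1] = (state.P[-2] + h * sigma * params.rho_P * params.T_hat) \
        / (1.0 + h * sigma)
    for name in ("D", "I12", "Ta", "A", "B"):
        arr = getattr(state, name)
        arr[-1] = arr[-2]
    state.C[-1] = params.rho_tot - state.D[-1] - state.T[-1]
    return state


# uniform initial levels (g/cm^3); the cell entries sum to rho_tot
_INITIAL_LEVELS = {"D": 2.0e-4, "T": 1.0e-4, "C": 0.4011,
                   "I12": 1.0e-10, "Ta": 1.0e-11}


def initial_state(R0: float,
                  params: ParameterSet,
                  n_intervals: int = 100) -> tuple[TumorState, RadialMesh]:
    """Uniform initial fields on a uniform mesh over [0, R0]."""
    if R0 <= 0:
        raise ValueError(f"initial radius must be positive, got {R0}")
    mesh = RadialMesh.uniform(R0, n_intervals, t=0.0)
    ones = np.ones(mesh.n_nodes)
    state = TumorState(
        D=_INITIAL_LEVELS["D"] * ones,
        T=_INITIAL_LEVELS["T"] * ones,
        C=_INITIAL_LEVELS["C"] * ones,
        I12=_INITIAL_LEVELS["I12"] * ones,
        Ta=_INITIAL_LEVELS["Ta"] * ones,
        P=params.rho_P * _INITIAL_LEVELS["T"] * ones,
        A=np.zeros(mesh.n_nodes),
        B=np.zeros(mesh.n_nodes),
        t=0.0,
    )
    return state, mesh
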