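"""Shared fixtures.  Expensive simulations are session-scoped and reused
by several tests; everything is generated at run time."""

from __future__ import annotations

import numpy as np
import pytest

import tumortx as tx


@pytest.fixture()
def params() -> tx.ParameterSet:
    return tx.ParameterSet()


@pytest.fixture(scope="session")
def control_result():
    """30-day no-drug mouse run at the reference resolution (N=100)."""
    return tx.run_control(check_plateau=False)


@pytest.fixture(scope="session")
def control_result_n50():
    """Same control run at half the resolution, for refinement checks."""
    return tx.simulate(tx.ParameterSet(), R0=0.5,
                       settings=tx.SolverSettings(n_intervals=50, t_end=30.0))


def make_uniform_state(params: tx.ParameterSet,
                       n_intervals: int = 20,
                       R: float = 0.5,
                       **levels) -> tuple[tx.TumorState, tx.RadialMesh]:
    """Spatially uniform state at given field levels (cell sum enforced)."""
    defaults = {"D": 4e-4, "T": 1e-3, "I12": 8e-10, "Ta": 3e-11,
                "P": 2.49e-10, "A": 0.0, "B": 0.0}
    defaults.update(levels)
    if "C" not in defaults:
        defaults["C"] = params.rho_tot - defaults["D"] - defaults["T"]
    mesh = tx.RadialMesh.uniform(R, n_intervals)
    ones = np.ones(mesh.n_nodes)
    state = tx.TumorState(**{k: v * ones for k, v in defaults.items()})
    return state, mesh
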