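"""Jitted inner loop of the moving-mesh integrator.

This mirrors, operation for operation, the reference implementation in
:mod:`model_core` / :mod:`solver` (derived fields, reaction terms,
velocity quadrature, nonuniform stencils, semi-implicit center node,
fluid re-interpolation, boundary conditions, regridding) but advances
many steps per call without Python overhead.  A consistency test keeps
the two paths in lock-step; any change here must be made in the
reference path too.

Field row order throughout: D, T, C, I12, Ta, P, A, B.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# rows
_D, _T, _C, _I12, _TA, _P, _A, _B = range(8)

# packed parameter-vector indices
(P_RHO_TOT, P_LAM_DC, P_K_C, P_D_D, P_LAM_TI12, P_K_I12, P_D_T, P_LAM_C,
 P_C_M, P_ETA, P_D_C, P_LAM_I12D, P_D_I12, P_A_TA, P_LAM_TAT, P_MU_TAB,
 P_D_TA, P_RHO_L, P_EPS_C, P_ALPHA_L, P_K_TA, P_RHO_M, P_ALPHA_T,
 P_ALPHA_MA, P_K_A, P_RHO_G, P_K_TQ1, P_K_TQ2, P_MU_PA, P_D_A, P_D_B,
 P_SIGMA0, P_T_HAT, P_RHO_P, P_DELTA_CELL, P_DELTA_I12, P_DELTA_TA,
 P_DELTA_A, P_DELTA_B, P_DELTA_MAX, P_BETA, P_EPS_GUARD, N_PARAMS) = range(43)


def pack_params(params) -> np.ndarray:
    """Flatten a ParameterSet into the kernel's constant vector."""
    pv = np.empty(N_PARAMS)
    pv[P_RHO_TOT] = params.rho_tot
    pv[P_LAM_DC] = params.lambda_DC_D0
    pv[P_K_C] = params.K_C
    pv[P_D_D] = params.d_D
    pv[P_LAM_TI12] = params.lambda_TI12_T0
    pv[P_K_I12] = params.K_I12
    pv[P_D_T] = params.d_T
    pv[P_LAM_C] = params.lambda_C
    pv[P_C_M] = params.C_M
    pv[P_ETA] = params.eta
    pv[P_D_C] = params.d_C
    pv[P_LAM_I12D] = params.lambda_I12D
    pv[P_D_I12] = params.d_I12
    pv[P_A_TA] = params.A_Talpha
    pv[P_LAM_TAT] = params.lambda_TalphaT
    pv[P_MU_TAB] = params.mu_TalphaB
    pv[P_D_TA] = params.d_Talpha
    pv[P_RHO_L] = params.rho_L
    pv[P_EPS_C] = params.eps_C
    pv[P_ALPHA_L] = params.alpha_L
    pv[P_K_TA] = params.K_Talpha
    pv[P_RHO_M] = params.rho_M
    pv[P_ALPHA_T] = params.alpha_T
    pv[P_ALPHA_MA] = params.alpha_MA
    pv[P_K_A] = params.K_A
    pv[P_RHO_G] = params.rho_G
    pv[P_K_TQ1] = params.K_TQ1
    pv[P_K_TQ2] = params.K_TQ2
    pv[P_MU_PA] = params.mu_PA
    pv[P_D_A] = params.d_A
    pv[P_D_B] = params.d_B
    pv[P_SIGMA0] = params.sigma_0
    pv[P_T_HAT] = params.T_hat
    pv[P_RHO_P] = params.rho_P
    pv[P_DELTA_CELL] = params.delta_cell
    pv[P_DELTA_I12] = params.delta_I12
    pv[P_DELTA_TA] = params.delta_Talpha
    pv[P_DELTA_A] = params.delta_A
    pv[P_DELTA_B] = params.delta_B
    pv[P_DELTA_MAX] = params.delta_max
    pv[P_BETA] = params.beta
    pv[P_EPS_GUARD] = 1.0e-12
    return pv


@njit(cache=True)
def _dose_rate(t, days, gammas, beta):
    rate = 0.0
    for k in range(days.size):
        if days[k] < t:
            rate += gammas[k] * np.exp(-beta * (t - days[k]))
    return rate


@njit(cache=True)
def _apply_bcs(X, r, pv):
    m = r.size
    h = r[m - 1] - r[m - 2]
    i12b = X[_I12, m - 1]
    sigma = pv[P_SIGMA0] * i12b / (pv[P_K_I12] + i12b)
    X[_T, m - 1] = (X[_T, m - 2] + h * sigma * pv[P_T_HAT]) / (1.0 + h * sigma)
    X[_P, m - 1] = (X[_P, m - 2] + h * sigma * pv[P_RHO_P] * pv[P_T_HAT]) \
        / (1.0 + h * sigma)
    X[_D, m - 1] = X[_D, m - 2]
    X[_I12, m - 1] = X[_I12, m - 2]
    X[_TA, m - 1] = X[_TA, m - 2]
    X[_A, m - 1] = X[_A, m - 2]
    X[_B, m - 1] = X[_B, m - 2]
    X[_C, m - 1] = pv[P_RHO_TOT] - X[_D, m - 1] - X[_T, m - 1]


@njit(cache=True)
def advance(X, r, t, t_stop, pv,
            days_a, gammas_a, days_b, gammas_b,
            safety, regrid_ratio, regrid_growth, R_last_regrid):
    """Advance the stacked state to ``t_stop`` in place.

    Returns (t, steps, clips, regrids, R_last_regrid, status) with
    status 0 = ok, 1 = non-finite values, 2 = mesh folded.
    """
    m = r.size
    delta = np.empty(8)
    delta[_D] = pv[P_DELTA_CELL]
    delta[_T] = pv[P_DELTA_CELL]
    delta[_C] = pv[P_DELTA_CELL]
    delta[_I12] = pv[P_DELTA_I12]
    delta[_TA] = pv[P_DELTA_TA]
    delta[_P] = pv[P_DELTA_CELL]
    delta[_A] = pv[P_DELTA_A]
    delta[_B] = pv[P_DELTA_B]

    F = np.empty((8, m))
    u = np.empty(m)
    r_new = np.empty(m)
    steps = 0
    clips = 0
    regrids = 0

    while t < t_stop - 1e-12:
        gA = _dose_rate(t, days_a, gammas_a, pv[P_BETA])
        gB = _dose_rate(t, days_b, gammas_b, pv[P_BETA])

        # derived fields, reactions and rate extrema in one pass
        maxB = 0.0
        maxTa = 0.0
        maxP = 0.0
        maxT = 0.0
        for i in range(m):
            Ti = X[_T, i]
            Ci = X[_C, i]
            Tai = X[_TA, i]
            Ai = X[_A, i]
            Pi = X[_P, i]
            Bi = X[_B, i]
            ta_sat = Tai / (pv[P_K_TA] + Tai)
            a_sat = Ai / (pv[P_K_A] + Ai)
            L = pv[P_RHO_L] * (Ti + pv[P_EPS_C] * Ci) \
                * (1.0 + pv[P_ALPHA_L] * ta_sat)
            TM = pv[P_RHO_M] * Ti * (1.0 + pv[P_ALPHA_T] * ta_sat
                                     * (1.0 + pv[P_ALPHA_MA] * a_sat))
            G = pv[P_RHO_G] * Ci
            f_q1 = 1.0 / (1.0 + Pi * L / pv[P_K_TQ1])
            f_q2 = 1.0 / (1.0 + TM * G / pv[P_K_TQ2])

            F[_D, i] = pv[P_LAM_DC] * Ci / (pv[P_K_C] + Ci) \
                - pv[P_D_D] * X[_D, i]
            F_T = pv[P_LAM_TI12] * X[_I12, i] / (pv[P_K_I12] + X[_I12, i]) \
                * f_q1 * f_q2 - pv[P_D_T] * Ti
            F[_T, i] = F_T
            F[_C, i] = pv[P_LAM_C] * Ci * (1.0 - Ci / pv[P_C_M]) \
                - pv[P_ETA] * Ti * Ci - pv[P_D_C] * Ci
            F[_I12, i] = pv[P_LAM_I12D] * X[_D, i] - pv[P_D_I12] * X[_I12, i]
            F[_TA, i] = pv[P_A_TA] + pv[P_LAM_TAT] * Ti \
                - pv[P_MU_TAB] * Tai * Bi - pv[P_D_TA] * Tai
            guard = Ti if Ti > pv[P_EPS_GUARD] else pv[P_EPS_GUARD]
            F[_P, i] = Pi / guard * F_T - pv[P_MU_PA] * Pi * Ai
            F[_A, i] = gA - pv[P_MU_PA] * Pi * Ai - pv[P_D_A] * Ai
            F[_B, i] = gB - pv[P_MU_TAB] * Tai * Bi - pv[P_D_B] * Bi

            if Bi > maxB:
                maxB = Bi
            if Tai > maxTa:
                maxTa = Tai
            if Pi > maxP:
                maxP = Pi
            if Ti > maxT:
                maxT = Ti

        # velocity by segment-exact quadrature of r^2 * S (S piecewise linear)
        u[0] = 0.0
        flux = 0.0
        for i in range(1, m):
            a = r[i - 1]
            b = r[i]
            Sa = F[_D, i - 1] + F[_T, i - 1] + F[_C, i - 1]
            Sb = F[_D, i] + F[_T, i] + F[_C, i]
            slope = (Sb - Sa) / (b - a)
            cubes = (b ** 3 - a ** 3) / 3.0
            flux += Sa * cubes + slope * ((b ** 4 - a ** 4) / 4.0 - a * cubes)
            u[i] = flux / (pv[P_RHO_TOT] * b * b)

        # combined diffusion + stiff-reaction step bound
        h_min = r[1] - r[0]
        for i in range(2, m):
            h = r[i] - r[i - 1]
            if h < h_min:
                h_min = h
        rate = pv[P_D_TA] + pv[P_MU_TAB] * maxB
        rr = pv[P_D_B] + pv[P_MU_TAB] * maxTa
        if rr > rate:
            rate = rr
        rr = pv[P_D_A] + pv[P_MU_PA] * maxP
        if rr > rate:
            rate = rr
        rr = pv[P_D_C] + pv[P_LAM_C] + pv[P_ETA] * maxT
        if rr > rate:
            rate = rr
        if pv[P_D_I12] > rate:
            rate = pv[P_D_I12]
        tau = safety / (2.0 * pv[P_DELTA_MAX] / (h_min * h_min) + rate)
        if tau > t_stop - t:
            tau = t_stop - t

        X_new = np.empty((8, m))
        # interior nodes: nonuniform three-point stencil
        for i in range(1, m - 1):
            h1 = r[i + 1] - r[i]
            hm1 = r[i - 1] - r[i]
            den1 = h1 * hm1 * (hm1 - h1)
            den2 = h1 * (h1 * hm1 - hm1 * hm1)
            Si = F[_D, i] + F[_T, i] + F[_C, i]
            div_u = Si / pv[P_RHO_TOT]
            for j in range(8):
                xc = X[j, i]
                xp = X[j, i + 1]
                xm = X[j, i - 1]
                first = (hm1 * hm1 * xp - h1 * h1 * xm
                         + (h1 * h1 - hm1 * hm1) * xc) / den1
                second = 2.0 * (hm1 * xp - h1 * xm + (h1 - hm1) * xc) / den2
                lap = second + 2.0 / r[i] * first
                val = xc + tau * (delta[j] * lap + F[j, i])
                if j == _D or j == _T or j == _C or j == _P:
                    val -= tau * xc * div_u
                X_new[j, i] = val
        # center node: semi-implicit diffusion exchange (see solver)
        S0 = F[_D, 0] + F[_T, 0] + F[_C, 0]
        div0 = S0 / pv[P_RHO_TOT]
        for j in range(8):
            a0 = 6.0 * delta[j] * tau / (r[1] * r[1])
            rhs = X[j, 0] + a0 * X[j, 1] + tau * F[j, 0]
            if j == _D or j == _T or j == _C or j == _P:
                rhs -= tau * X[j, 0] * div0
            X_new[j, 0] = rhs / (1.0 + a0)
        # boundary node: reaction/advection only (diffusion term dropped);
        # almost everything here is overwritten by the BCs, but the I12
        # value feeds the Robin influx coefficient
        Sb_ = F[_D, m - 1] + F[_T, m - 1] + F[_C, m - 1]
        divb = Sb_ / pv[P_RHO_TOT]
        for j in range(8):
            val = X[j, m - 1] + tau * F[j, m - 1]
            if j == _D or j == _T or j == _C or j == _P:
                val -= tau * X[j, m - 1] * divb
            X_new[j, m - 1] = val

        # move the mesh
        for i in range(m):
            r_new[i] = r[i] + u[i] * tau
        ok = r_new[m - 1] > 0.0
        for i in range(1, m):
            if r_new[i] <= r_new[i - 1]:
                ok = False
        if not ok:
            return t, steps, clips, regrids, R_last_regrid, 2

        # fluids were updated at the old positions; re-interpolate
        for j in (_I12, _TA, _A, _B):
            row = np.interp(r_new, r, X_new[j])
            for i in range(m):
                X_new[j, i] = row[i]

        finite = True
        for j in range(8):
            for i in range(m):
                v = X_new[j, i]
                if not np.isfinite(v):
                    finite = False
                if v < 0.0:
                    clips += 1
                    X_new[j, i] = 0.0
        if not finite:
            return t, steps, clips, regrids, R_last_regrid, 1

        for i in range(m):
            r[i] = r_new[i]
        _apply_bcs(X_new, r, pv)
        for j in range(8):
            for i in range(m):
                X[j, i] = X_new[j, i]

        t += tau
        steps += 1

        # regrid onto a uniform mesh when spacing degrades or R has grown
        h_max = r[1] - r[0]
        h_min2 = h_max
        for i in range(2, m):
            h = r[i] - r[i - 1]
            if h > h_max:
                h_max = h
            if h < h_min2:
                h_min2 = h
        if (h_max / h_min2 > regrid_ratio
                or r[m - 1] > (1.0 + regrid_growth) * R_last_regrid):
            r_uni = np.linspace(0.0, r[m - 1], m)
            for j in range(8):
                row = np.interp(r_uni, r, X[j])
                for i in range(m):
                    X[j, i] = row[i]
            for i in range(m):
                r[i] = r_uni[i]
            R_last_regrid = r[m - 1]
            regrids += 1

    return t, steps, clips, regrids, R_last_regrid, 0
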