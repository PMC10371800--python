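"""Fast single-shooting rollout kernel for the controller.

Numerically identical to ``twin.simulate_fixed_step`` followed by the
trapezoidal tracking objective, but operating on packed arrays (and JIT
compiled with numba when available) so the SLSQP finite-difference loop is
cheap.  Any change to the twin's rate laws must be mirrored here; the test
suite asserts bit-level agreement between the two paths.

State vector: [V, Xv, Xd, glc, gln, asn, ala, lac, nh4, P]
Flux vector:  [glc, gln, asn, ala, lac, nh4, biomass]
"""

from __future__ import annotations

import math

import numpy as np

from .kinetics import KineticParameters

__all__ = ["pack_params", "rollout_objective", "N_FLUX"]

N_FLUX = 7


def pack_params(p: KineticParameters) -> np.ndarray:
    return np.array(
        [
            p.mu_max, p.K_glc, p.K_gln, p.K_asn, p.KI_lac, p.KI_amm,
            p.kd_0, p.kd_amm,
            p.Y_xg, p.m_glc, p.K_mglc,
            p.Y_lg, p.q_lac_max, p.K_lac, p.lac_switch, p.lac_switch_width,
            p.q_max["gln"], p.K["gln"], p.q_max["asn"], p.K["asn"],
            p.Y_amm_gln, p.Y_amm_asn, p.Y_ala_asn,
            p.alpha, p.beta,
            p.KI_glc,
        ]
    )


def _interp(t, knots, vals):
    n = knots.shape[0]
    if t <= knots[0]:
        return vals[0]
    if t >= knots[n - 1]:
        return vals[n - 1]
    for i in range(1, n):
        if t <= knots[i]:
            w = (t - knots[i - 1]) / (knots[i] - knots[i - 1])
            return vals[i - 1] + w * (vals[i] - vals[i - 1])
    return vals[n - 1]


def _rhs(t, y, knots, u_fin, u_fout, u_cglc, f_other, pp, dy):
    V = y[0] if y[0] > 1e-12 else 1e-12
    Xv = y[1] if y[1] > 0.0 else 0.0
    Xd = y[2] if y[2] > 0.0 else 0.0
    glc = y[3] if y[3] > 0.0 else 0.0
    gln = y[4] if y[4] > 0.0 else 0.0
    asn = y[5] if y[5] > 0.0 else 0.0
    ala = y[6] if y[6] > 0.0 else 0.0
    lac = y[7] if y[7] > 0.0 else 0.0
    amm = y[8] if y[8] > 0.0 else 0.0
    P = y[9] if y[9] > 0.0 else 0.0

    F_in = _interp(t, knots, u_fin)
    F_out = _interp(t, knots, u_fout)
    c_glc_feed = _interp(t, knots, u_cglc)

    ki_glc = 1.0 if math.isinf(pp[25]) else pp[25] / (pp[25] + glc)
    mu = (
        pp[0]
        * glc / (pp[1] + glc)
        * ki_glc
        * gln / (pp[2] + gln)
        * asn / (pp[3] + asn)
        * pp[4] / (pp[4] + lac)
        * pp[5] / (pp[5] + amm)
    )
    mu_d = pp[6] + pp[7] * amm
    q_glc_up = mu / pp[8] + pp[9] * glc / (pp[10] + glc)
    if glc == 0.0:
        q_glc_up = 0.0
    q_gln_up = pp[16] * gln / (pp[17] + gln)
    q_asn_up = pp[18] * asn / (pp[19] + asn)
    w = 1.0 / (1.0 + math.exp(-(glc - pp[14]) / pp[15]))
    q_lac = w * pp[11] * q_glc_up - (1.0 - w) * pp[12] * lac / (pp[13] + lac)
    q_amm = pp[20] * q_gln_up + pp[21] * q_asn_up
    q_ala = pp[22] * q_asn_up

    dy[0] = F_in - F_out
    dy[1] = (mu - mu_d) * Xv - F_in * Xv / V
    dy[2] = mu_d * Xv - F_in * Xd / V
    dy[3] = (F_in * c_glc_feed - F_in * glc) / V - q_glc_up * Xv
    dy[4] = (F_in * f_other[1] - F_in * gln) / V - q_gln_up * Xv
    dy[5] = (F_in * f_other[2] - F_in * asn) / V - q_asn_up * Xv
    dy[6] = (F_in * f_other[3] - F_in * ala) / V + q_ala * Xv
    dy[7] = (F_in * f_other[4] - F_in * lac) / V + q_lac * Xv
    dy[8] = (F_in * f_other[5] - F_in * amm) / V + q_amm * Xv
    dy[9] = (pp[23] * mu + pp[24]) * Xv - F_in * P / V


def _fluxes(y, pp, out):
    Xv = y[1]
    if Xv <= 0.0:
        for i in range(N_FLUX):
            out[i] = 0.0
        return
    glc = y[3] if y[3] > 0.0 else 0.0
    gln = y[4] if y[4] > 0.0 else 0.0
    asn = y[5] if y[5] > 0.0 else 0.0
    lac = y[7] if y[7] > 0.0 else 0.0
    amm = y[8] if y[8] > 0.0 else 0.0
    ki_glc = 1.0 if math.isinf(pp[25]) else pp[25] / (pp[25] + glc)
    mu = (
        pp[0]
        * glc / (pp[1] + glc)
        * ki_glc
        * gln / (pp[2] + gln)
        * asn / (pp[3] + asn)
        * pp[4] / (pp[4] + lac)
        * pp[5] / (pp[5] + amm)
    )
    q_glc_up = mu / pp[8] + pp[9] * glc / (pp[10] + glc)
    if glc == 0.0:
        q_glc_up = 0.0
    q_gln_up = pp[16] * gln / (pp[17] + gln)
    q_asn_up = pp[18] * asn / (pp[19] + asn)
    w = 1.0 / (1.0 + math.exp(-(glc - pp[14]) / pp[15]))
    out[0] = -q_glc_up
    out[1] = -q_gln_up
    out[2] = -q_asn_up
    out[3] = pp[22] * q_asn_up
    out[4] = w * pp[11] * q_glc_up - (1.0 - w) * pp[12] * lac / (pp[13] + lac)
    out[5] = pp[20] * q_gln_up + pp[21] * q_asn_up
    out[6] = mu


def rollout_objective(
    y0: np.ndarray,
    t0: float,
    t1: float,
    n_steps: int,
    knots: np.ndarray,
    u_fin: np.ndarray,
    u_fout: np.ndarray,
    u_cglc: np.ndarray,
    f_other: np.ndarray,
    pp: np.ndarray,
    out_idx: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
) -> float:
    """RK4 rollout on n_steps uniform steps; trapezoidal OF on the output
    subgrid ``out_idx`` (step indices) against ``targets`` (n_out x 7)."""
    h = (t1 - t0) / n_steps
    y = y0.copy()
    k1 = np.zeros(10)
    k2 = np.zeros(10)
    k3 = np.zeros(10)
    k4 = np.zeros(10)
    flux = np.zeros(N_FLUX)
    n_out = out_idx.shape[0]
    sq = np.zeros(n_out)
    times = np.zeros(n_out)
    j = 0
    if out_idx[0] == 0:
        _fluxes(y, pp, flux)
        acc = 0.0
        for f in range(N_FLUX):
            r = flux[f] - targets[0, f]
            acc += weights[f] * r * r
        sq[0] = acc
        times[0] = t0
        j = 1
    for k in range(n_steps):
        t = t0 + k * h
        _rhs(t, y, knots, u_fin, u_fout, u_cglc, f_other, pp, k1)
        _rhs(t + 0.5 * h, y + 0.5 * h * k1, knots, u_fin, u_fout, u_cglc, f_other, pp, k2)
        _rhs(t + 0.5 * h, y + 0.5 * h * k2, knots, u_fin, u_fout, u_cglc, f_other, pp, k3)
        _rhs(t + h, y + h * k3, knots, u_fin, u_fout, u_cglc, f_other, pp, k4)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for i in range(1, 10):
            if y[i] < 0.0:
                y[i] = 0.0
        if y[0] < 1e-12:
            y[0] = 1e-12
        if j < n_out and out_idx[j] == k + 1:
            _fluxes(y, pp, flux)
            acc = 0.0
            for f in range(N_FLUX):
                r = flux[f] - targets[j, f]
                acc += weights[f] * r * r
            sq[j] = acc
            times[j] = t0 + (k + 1) * h
            j += 1
    total = 0.0
    for i in range(1, n_out):
        total += 0.5 * (sq[i - 1] + sq[i]) * (times[i] - times[i - 1])
    return total


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _interp = njit(cache=False)(_interp)
    _rhs = njit(cache=False)(_rhs)
    _fluxes = njit(cache=False)(_fluxes)
    rollout_objective = njit(cache=False)(rollout_objective)
except ImportError:  # pure-python fallback, same numerics
    pass
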