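"""Fed-batch reactor digital twin.

ODE mass balances for volume, viable/dead cells, extracellular metabolites
and antibody, driven by a piecewise-linear :class:`FeedPolicy`:

    dV/dt       = F_in - F_out
    d(V*Xv)/dt  = (mu - mu_d)*V*Xv - F_out*Xv
    d(V*Xd)/dt  = mu_d*V*Xv - F_out*Xd
    d(V*C_i)/dt = F_in*C_feed_i - F_out*C_i + q_i*Xv*V
    d(V*P)/dt   = (alpha*mu + beta)*Xv*V - F_out*P

with q_i the specific exchange rates (secretion > 0).  Dead cells are
tracked but inert (no lysis release).  Concentrations are clipped at zero in
rate evaluation, with clip events logged on the trajectory.

Units: h, L, mmol/L, 1e9 cells/L, mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticParameters, death_rate, growth_rate, specific_rates

__all__ = [
    "ReactorState",
    "FeedPolicy",
    "SimulationTrajectory",
    "rhs",
    "simulate",
    "simulate_fixed_step",
    "observed_fluxes",
]

#: extracellular species carried by the twin state, in state-vector order
SPECIES: tuple[str, ...] = ("glc", "gln", "asn", "ala", "lac", "nh4")


@dataclass
class ReactorState:
    t: float                      # h
    V: float                      # L
    Xv: float                     # 1e9 cells/L
    Xd: float                     # 1e9 cells/L
    C: dict[str, float]           # mmol/L per species
    P: float = 0.0                # mg/L antibody

    def validate(self) -> None:
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if self.Xv < 0 or self.Xd < 0 or self.P < 0:
            raise ValueError("cell densities and titre must be nonnegative")
        for s, c in self.C.items():
            if c < 0:
                raise ValueError(f"concentration of {s!r} is negative ({c})")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.V, self.Xv, self.Xd]
            + [self.C.get(s, 0.0) for s in SPECIES]
            + [self.P]
        )

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray) -> "ReactorState":
        return cls(
            t=t,
            V=float(y[0]),
            Xv=float(y[1]),
            Xd=float(y[2]),
            C={s: float(y[3 + i]) for i, s in enumerate(SPECIES)},
            P=float(y[-1]),
        )


@dataclass
class FeedPolicy:
    """Piecewise-linear manipulated-variable profiles on a knot grid.

    ``F_in``/``F_out`` in L/h, ``C_feed_glc`` in mmol/L.  ``C_feed_other``
    holds the fixed feed concentrations of the non-glucose species.
    """

    knots: np.ndarray             # strictly increasing times, h
    F_in: np.ndarray              # L/h at knots
    F_out: np.ndarray             # L/h at knots
    C_feed_glc: np.ndarray        # mmol/L at knots
    C_feed_other: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.F_in = np.asarray(self.F_in, dtype=float)
        self.F_out = np.asarray(self.F_out, dtype=float)
        self.C_feed_glc = np.asarray(self.C_feed_glc, dtype=float)
        n = self.knots.size
        if n < 2 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be >= 2 strictly increasing times")
        for name in ("F_in", "F_out", "C_feed_glc"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must have one value per knot")

    @property
    def t0(self) -> float:
        return float(self.knots[0])

    @property
    def t1(self) -> float:
        return float(self.knots[-1])

    def _interp(self, t: float, vals: np.ndarray) -> float:
        if t < self.knots[0] - 1e-9 or t > self.knots[-1] + 1e-9:
            raise ValueError(
                f"policy defined on [{self.knots[0]}, {self.knots[-1]}] h, asked at t={t}"
            )
        return float(np.interp(t, self.knots, vals))

    def at(self, t: float) -> tuple[float, float, float]:
        """(F_in, F_out, C_feed_glc) at time t."""
        return (
            self._interp(t, self.F_in),
            self._interp(t, self.F_out),
            self._interp(t, self.C_feed_glc),
        )

    def feed_concentrations(self, t: float) -> dict[str, float]:
        out = dict(self.C_feed_other)
        out["glc"] = self._interp(t, self.C_feed_glc)
        return out

    def restricted(self, t0: float, t1: float) -> "FeedPolicy":
        """Policy restricted to [t0, t1], adding knots at the cut points."""
        ts = np.union1d(
            self.knots[(self.knots >= t0) & (self.knots <= t1)], [t0, t1]
        )
        return FeedPolicy(
            knots=ts,
            F_in=np.interp(ts, self.knots, self.F_in),
            F_out=np.interp(ts, self.knots, self.F_out),
            C_feed_glc=np.interp(ts, self.knots, self.C_feed_glc),
            C_feed_other=dict(self.C_feed_other),
        )

    @staticmethod
    def concatenate(policies: list["FeedPolicy"]) -> "FeedPolicy":
        """Join contiguous policy segments into one policy."""
        if not policies:
            raise ValueError("nothing to concatenate")
        knots = [policies[0].knots]
        fin = [policies[0].F_in]
        fout = [policies[0].F_out]
        cfg = [policies[0].C_feed_glc]
        for prev, seg in zip(policies, policies[1:]):
            if abs(seg.t0 - prev.t1) > 1e-9:
                raise ValueError("segments are not contiguous")
            knots.append(seg.knots[1:])
            fin.append(seg.F_in[1:])
            fout.append(seg.F_out[1:])
            cfg.append(seg.C_feed_glc[1:])
        return FeedPolicy(
            knots=np.concatenate(knots),
            F_in=np.concatenate(fin),
            F_out=np.concatenate(fout),
            C_feed_glc=np.concatenate(cfg),
            C_feed_other=dict(policies[0].C_feed_other),
        )


def rhs(t: float, y: np.ndarray, policy: FeedPolicy, p: KineticParameters) -> np.ndarray:
    """Time derivative of the packed state vector [V, Xv, Xd, C..., P]."""
    V = max(float(y[0]), 1e-12)
    Xv = max(float(y[1]), 0.0)
    Xd = max(float(y[2]), 0.0)
    C = {s: max(float(y[3 + i]), 0.0) for i, s in enumerate(SPECIES)}
    P = max(float(y[-1]), 0.0)

    F_in, F_out, _ = policy.at(t)
    C_feed = policy.feed_concentrations(t)

    mu = growth_rate(C, p)
    mu_d = death_rate(C, p)
    q = specific_rates(C, p)

    dV = F_in - F_out
    # d(V*X)/dt expansions: dX/dt = (balance - X*dV/dt)/V
    dXv = (mu - mu_d) * Xv - F_in * Xv / V
    dXd = mu_d * Xv - F_in * Xd / V
    dC = [
        (F_in * C_feed.get(s, 0.0) - F_in * C[s]) / V + q[s] * Xv
        for s in SPECIES
    ]
    dP = (p.alpha * mu + p.beta) * Xv - F_in * P / V

    return np.array([dV, dXv, dXd] + dC + [dP])


@dataclass
class SimulationTrajectory:
    grid: np.ndarray                         # output times, h
    states: list[ReactorState]
    fluxes: pd.DataFrame                     # one column per tracked flux id
    glucose_fed: np.ndarray                  # cumulative mmol at grid times
    clip_events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def final_state(self) -> ReactorState:
        return self.states[-1]

    @property
    def total_glucose_fed(self) -> float:
        return float(self.glucose_fed[-1])

    @property
    def final_antibody_mass(self) -> float:
        """Antibody mass P*V at the last grid point (mg)."""
        s = self.final_state
        return s.P * s.V

    @property
    def ivcd(self) -> float:
        """Integral of viable cell density over time (1e9 cells * h / L)."""
        xv = np.array([s.Xv for s in self.states])
        return float(np.trapezoid(xv, self.grid))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            row = {"t": s.t, "V": s.V, "Xv": s.Xv, "Xd": s.Xd, "P": s.P}
            row.update({f"C_{k}": v for k, v in s.C.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _glucose_fed_rate(t: float, policy: FeedPolicy) -> float:
    F_in, _, C_glc = policy.at(t)
    return F_in * C_glc


def _cumulative_glucose(grid: np.ndarray, policy: FeedPolicy) -> np.ndarray:
    """Exact integral of F_in(t)*C_feed_glc(t): both are piecewise linear,
    so the product is piecewise quadratic; Simpson on knot-refined panels."""
    ts = np.union1d(grid, policy.knots[(policy.knots >= grid[0]) & (policy.knots <= grid[-1])])
    cum = np.zeros(ts.size)
    for i in range(1, ts.size):
        a, b = ts[i - 1], ts[i]
        mid = 0.5 * (a + b)
        fa = _glucose_fed_rate(a, policy)
        fm = _glucose_fed_rate(mid, policy)
        fb = _glucose_fed_rate(b, policy)
        cum[i] = cum[i - 1] + (b - a) / 6.0 * (fa + 4.0 * fm + fb)
    return np.interp(grid, ts, cum)


def _flux_row(state: ReactorState, p: KineticParameters) -> dict[str, float]:
    # with no viable cells there is no realized specific flux, by convention
    if state.Xv <= 0.0:
        return {s: 0.0 for s in (*SPECIES, "biomass")}
    row = dict(specific_rates(state.C, p))
    row["biomass"] = growth_rate(state.C, p)
    return row


def simulate(
    x0: ReactorState,
    policy: FeedPolicy,
    p: KineticParameters,
    t_end: float,
    output_dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationTrajectory:
    """Integrate the twin with an adaptive stiff-capable solver (LSODA).

    Integration restarts at every policy knot so the piecewise-linear inputs
    never present a derivative kink inside a solver step.
    """
    x0.validate()
    if not t_end > x0.t:
        raise ValueError("t_end must exceed the initial time")
    if policy.t0 > x0.t + 1e-9 or policy.t1 < t_end - 1e-9:
        raise ValueError("policy does not span the simulation window")

    grid = np.arange(x0.t, t_end + 0.5 * output_dt, output_dt)
    if grid[-1] < t_end - 1e-9:
        grid = np.append(grid, t_end)
    grid[-1] = min(grid[-1], t_end)

    seg_edges = np.union1d(
        policy.knots[(policy.knots > x0.t) & (policy.knots < t_end)], [x0.t, t_end]
    )
    y = x0.to_vector()
    clip_events: list[tuple[float, str]] = []
    ys = {float(x0.t): y.copy()}
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        t_eval = grid[(grid > a) & (grid <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            args=(policy, p),
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=np.union1d(t_eval, [b]),
            max_step=np.inf,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if sol.t.size else a:.3f} h: "
                f"{sol.message}"
            )
        for tk, yk in zip(sol.t, sol.y.T):
            neg = yk[3:-1] < 0
            if np.any(yk[3:-1] < -1e-9):
                for i in np.where(neg)[0]:
                    clip_events.append((float(tk), SPECIES[i]))
            ys[float(tk)] = np.maximum(yk, np.concatenate(([1e-12], np.zeros(yk.size - 1))))
        y = ys[float(b)]

    states = []
    for t in grid:
        yk = ys[float(t)]
        yk = yk.copy()
        yk[1:] = np.maximum(yk[1:], 0.0)
        states.append(ReactorState.from_vector(float(t), yk))
    fluxes = pd.DataFrame([_flux_row(s, p) for s in states], index=grid)
    return SimulationTrajectory(
        grid=grid,
        states=states,
        fluxes=fluxes,
        glucose_fed=_cumulative_glucose(grid, policy),
        clip_events=clip_events,
    )


def simulate_fixed_step(
    x0: ReactorState,
    policy: FeedPolicy,
    p: KineticParameters,
    t_end: float,
    dt: float = 0.5,
) -> SimulationTrajectory:
    """Fixed-step RK4 integration on a uniform grid.

    This is the controller's fast internal prediction model: a deterministic
    step count keeps finite-difference gradients smooth.  The plant-side
    twin uses :func:`simulate`.
    """
    x0.validate()
    n = max(1, int(round((t_end - x0.t) / dt)))
    grid = x0.t + (t_end - x0.t) * np.arange(n + 1) / n
    h = grid[1] - grid[0]
    y = x0.to_vector()
    states = [ReactorState.from_vector(float(grid[0]), y)]
    for k in range(n):
        t = grid[k]
        k1 = rhs(t, y, policy, p)
        k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1, policy, p)
        k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2, policy, p)
        k4 = rhs(t + h, y + h * k3, policy, p)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y[1:] = np.maximum(y[1:], 0.0)
        y[0] = max(y[0], 1e-12)
        states.append(ReactorState.from_vector(float(grid[k + 1]), y))
    fluxes = pd.DataFrame([_flux_row(s, p) for s in states], index=grid)
    return SimulationTrajectory(
        grid=grid,
        states=states,
        fluxes=fluxes,
        glucose_fed=_cumulative_glucose(grid, policy),
    )


def observed_fluxes(traj: SimulationTrajectory) -> pd.DataFrame:
    """Realized specific fluxes per output time, same ids/sign convention as
    the FBA stage-target table (exchange metabolite ids plus ``biomass``)."""
    return traj.fluxes.copy()
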