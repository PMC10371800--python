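"""Stage-wise flux balance analysis.

For each of the five fed-batch culture stages, biomass flux is maximized
subject to steady-state mass balance ``S v = 0``, non-negativity of
irreversible fluxes and stage-specific box bounds.  Because the biomass
optimum is generally degenerate, a second phase minimizes ``sum(v**2)`` at
the fixed optimal biomass value, which makes the resulting target flux table
unique and reproducible.

Flux units are mmol per 1e9 cells per hour; the biomass flux is h^-1.
Exchange sign convention: positive = secretion, negative = uptake.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .network import StoichiometricNetwork

__all__ = [
    "CultureStage",
    "StageBounds",
    "FBASolution",
    "StageTargetTable",
    "FBAError",
    "InfeasibleError",
    "UnboundedError",
    "solve_fba",
    "compute_stage_targets",
    "read_stage_bounds",
    "DEFAULT_BIG_M",
]

DEFAULT_BIG_M = 1000.0

#: mass-balance residual tolerance relative to max(1, ||v||_inf)
MASS_BALANCE_TOL = 1e-8
#: slack allowed on box bounds
BOUND_TOL = 1e-9


class CultureStage(enum.Enum):
    """The five fed-batch culture phases, in chronological order."""

    early_exponential = 0
    mid_exponential = 1
    late_exponential = 2
    early_stationary = 3
    late_stationary = 4

    def __lt__(self, other: "CultureStage") -> bool:
        if not isinstance(other, CultureStage):
            return NotImplemented
        return self.value < other.value


STAGES: tuple[CultureStage, ...] = tuple(CultureStage)


class FBAError(RuntimeError):
    pass


class InfeasibleError(FBAError):
    pass


class UnboundedError(FBAError):
    pass


@dataclass
class StageBounds:
    """Per-stage flux bounds; reactions absent from both maps get big-M."""

    stage: CultureStage
    lb: dict[str, float] = field(default_factory=dict)
    ub: dict[str, float] = field(default_factory=dict)

    def arrays(
        self, net: StoichiometricNetwork, big_m: float = DEFAULT_BIG_M
    ) -> tuple[np.ndarray, np.ndarray]:
        """Dense (lb, ub) in network reaction order.

        Defaults: reversible reactions [-M, M], irreversible [0, M]; explicit
        entries override but irreversible lower bounds are floored at 0.
        """
        n = len(net.reactions)
        lo = np.empty(n)
        hi = np.empty(n)
        for j, rxn in enumerate(net.reactions):
            lo[j] = self.lb.get(rxn.id, -big_m if rxn.reversible else 0.0)
            hi[j] = self.ub.get(rxn.id, big_m)
            if not rxn.reversible:
                lo[j] = max(lo[j], 0.0)
        bad = np.where(lo > hi)[0]
        if bad.size:
            rid = net.reactions[bad[0]].id
            raise InfeasibleError(
                f"stage {self.stage.name}: lb > ub for reaction {rid!r} "
                f"({lo[bad[0]]} > {hi[bad[0]]})"
            )
        return lo, hi


@dataclass
class FBASolution:
    v: dict[str, float]
    objective: float
    status: str

    def as_array(self, net: StoichiometricNetwork) -> np.ndarray:
        return np.array([self.v[r.id] for r in net.reactions])


def _solve_lp(
    S: np.ndarray, c: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, str]:
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError("FBA LP infeasible under the supplied bounds")
    if res.status == 3:
        raise UnboundedError(
            "FBA LP unbounded; supply finite bounds (or rely on the big-M default)"
        )
    if not res.success:
        raise FBAError(f"LP solver failure: {res.message}")
    return res.x, "optimal"


def _min_norm_at_optimum(
    S: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    c: np.ndarray,
    v0: np.ndarray,
    obj: float,
) -> np.ndarray:
    """Phase 2: min ||v||^2 s.t. S v = 0, c'v = obj, lo <= v <= hi."""
    A = np.vstack([S, c])
    b = np.zeros(A.shape[0])
    b[-1] = obj
    res = minimize(
        lambda v: float(v @ v),
        v0,
        jac=lambda v: 2.0 * v,
        bounds=list(zip(lo, hi)),
        constraints=[{"type": "eq", "fun": lambda v: A @ v - b, "jac": lambda v: A}],
        method="SLSQP",
        options={"maxiter": 400, "ftol": 1e-14},
    )
    v = res.x if res.success else v0
    # keep only if it actually preserves feasibility and the optimum
    r = max(1.0, float(np.max(np.abs(v))))
    if (
        np.max(np.abs(S @ v)) > MASS_BALANCE_TOL * r
        or abs(c @ v - obj) > 1e-7 * max(1.0, abs(obj))
        or np.any(v < lo - 1e-8)
        or np.any(v > hi + 1e-8)
    ):
        return v0
    return np.clip(v, lo, hi)


def solve_fba(
    net: StoichiometricNetwork,
    bounds: StageBounds,
    big_m: float = DEFAULT_BIG_M,
    minimize_norm: bool = True,
) -> FBASolution:
    """Maximize biomass flux subject to S v = 0 and box bounds.

    Among alternate optima the solution of minimal Euclidean norm (at the
    fixed optimal biomass value) is returned, so targets are unique.
    """
    S = net.S
    lo, hi = bounds.arrays(net, big_m=big_m)
    c = np.zeros(len(net.reactions))
    c[net.reactions.index(net.biomass_reaction)] = 1.0
    v, status = _solve_lp(S, c, lo, hi)
    obj = float(c @ v)
    if minimize_norm:
        v = _min_norm_at_optimum(S, lo, hi, c, v, obj)
    resid = float(np.max(np.abs(S @ v)))
    scale = max(1.0, float(np.max(np.abs(v))))
    if resid > MASS_BALANCE_TOL * scale:
        raise FBAError(f"mass-balance residual {resid:.2e} exceeds tolerance")
    return FBASolution(
        v={r.id: float(x) for r, x in zip(net.reactions, v)},
        objective=obj,
        status=status,
    )


def tracked_flux_ids(net: StoichiometricNetwork) -> list[str]:
    """Exchange fluxes of extracellular species (keyed by metabolite id)
    plus ``biomass``; product exchanges are excluded (reported separately)."""
    ids: list[str] = []
    for m in net.metabolites:
        if not m.extracellular:
            continue
        ex = net.exchange_for(m.id)
        if ex is None or ex.is_product:
            continue
        ids.append(m.id)
    ids.append("biomass")
    return ids


@dataclass
class StageTargetTable:
    """Per-stage constant target exchange fluxes produced by FBA.

    ``targets[stage][flux_id]`` with flux ids being metabolite ids for
    exchanges, ``"biomass"`` for the growth flux, and ``"product"`` for the
    (reported, not tracked) product secretion flux.
    """

    targets: dict[CultureStage, dict[str, float]]
    tracked: list[str]

    def target_at(self, stage: CultureStage, flux_id: str) -> float:
        return self.targets[stage][flux_id]

    def to_frame(self) -> pd.DataFrame:
        rows = {s.name: self.targets[s] for s in STAGES}
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("stage").to_csv(path)


def compute_stage_targets(
    net: StoichiometricNetwork,
    all_bounds: list[StageBounds],
    big_m: float = DEFAULT_BIG_M,
) -> StageTargetTable:
    """Run FBA per culture stage and tabulate tracked exchange targets."""
    by_stage = {b.stage: b for b in all_bounds}
    if set(by_stage) != set(STAGES) or len(all_bounds) != len(STAGES):
        raise ValueError("need exactly one StageBounds per CultureStage")
    tracked = tracked_flux_ids(net)
    biomass_id = net.biomass_reaction.id
    table: dict[CultureStage, dict[str, float]] = {}
    for stage in STAGES:
        try:
            sol = solve_fba(net, by_stage[stage], big_m=big_m)
        except FBAError as exc:
            raise type(exc)(f"stage {stage.name}: {exc}") from exc
        row: dict[str, float] = {}
        for fid in tracked:
            if fid == "biomass":
                row[fid] = sol.v[biomass_id]
            else:
                ex = net.exchange_for(fid)
                assert ex is not None
                row[fid] = sol.v[ex.id]
        prod = [r for r in net.reactions if r.is_product and r.is_exchange]
        if prod:
            row["product"] = sol.v[prod[0].id]
        table[stage] = row
    return StageTargetTable(targets=table, tracked=tracked)


def read_stage_bounds(path) -> list[StageBounds]:
    """Read the stage-bounds TSV (columns reaction_id, stage, lb, ub)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"reaction_id", "stage", "lb", "ub"}
    if set(df.columns) != expected:
        raise ValueError(f"stage bounds file must have columns {sorted(expected)}")
    out = {s: StageBounds(stage=s) for s in STAGES}
    for _, row in df.iterrows():
        stage = CultureStage[row["stage"]]
        if pd.notna(row["lb"]):
            out[stage].lb[row["reaction_id"]] = float(row["lb"])
        if pd.notna(row["ub"]):
            out[stage].ub[row["reaction_id"]] = float(row["ub"])
    return [out[s] for s in STAGES]


def write_stage_bounds(all_bounds: list[StageBounds], path) -> None:
    rows = []
    for sb in all_bounds:
        for rid in sorted(set(sb.lb) | set(sb.ub)):
            rows.append(
                {
                    "reaction_id": rid,
                    "stage": sb.stage.name,
                    "lb": sb.lb.get(rid, ""),
                    "ub": sb.ub.get(rid, ""),
                }
            )
    pd.DataFrame(rows, columns=["reaction_id", "stage", "lb", "ub"]).to_csv(
        path, sep="\t", index=False
    )
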