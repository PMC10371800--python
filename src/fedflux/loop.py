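"""Closed-loop orchestration and campaign metrics.

The receding-horizon loop: at every control-interval boundary, read the
twin state, optimize the feeding profile over the (batch-end-truncated)
horizon, implement only the first interval's segment on the plant-side twin,
and repeat.  The concatenated implemented segments form one continuous
policy, so a closed-loop run can be replayed open-loop.

Campaign metrics follow the batch-end comparison of the study design:
final antibody mass (mg) and concentration (mg/L), total glucose fed (mmol)
and percent improvement over an open-loop baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import ControlConfig, HorizonSolution, optimize_horizon
from .fba import CultureStage, STAGES, StageTargetTable
from .kinetics import KineticParameters
from .twin import FeedPolicy, ReactorState, SimulationTrajectory, simulate

__all__ = [
    "StageSchedule",
    "CampaignConfig",
    "CampaignResult",
    "run_closed_loop",
    "run_open_loop",
    "compare_campaigns",
    "tracking_report",
]


@dataclass(frozen=True)
class StageSchedule:
    """Six breakpoints delimiting the five culture-stage windows (h).

    Windows are left-closed/right-open; the final window is right-closed.
    """

    breakpoints: tuple[float, ...] = (0.0, 72.0, 144.0, 216.0, 288.0, 360.0)

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) != 6 or any(b <= a for a, b in zip(bp, bp[1:])):
            raise ValueError("need 6 strictly increasing breakpoints")

    @property
    def t_start(self) -> float:
        return self.breakpoints[0]

    @property
    def t_end(self) -> float:
        return self.breakpoints[-1]

    def stage_at(self, t: float) -> CultureStage:
        bp = self.breakpoints
        if t < bp[0] or t > bp[-1]:
            raise ValueError(f"t={t} outside the batch window [{bp[0]}, {bp[-1]}]")
        for i in range(5):
            if t < bp[i + 1]:
                return STAGES[i]
        return STAGES[4]


@dataclass
class CampaignConfig:
    batch_duration: float
    schedule: StageSchedule
    control: ControlConfig
    params: KineticParameters
    x0: ReactorState
    baseline_policy: FeedPolicy
    targets: StageTargetTable
    feed_concentrations: dict[str, float] = field(default_factory=dict)
    output_dt: float = 1.0
    reoptimize: str = "interval"       # "interval" | "stage"
    #: the controller's internal model parameters — an *estimate* of the
    #: plant's kinetics; defaults to the true plant parameters
    controller_params: KineticParameters | None = None
    #: glucose concentration of the feed line before the first control
    #: action (mmol/L); anchors the rate-of-change limit at batch start
    initial_glc_feed: float = 0.0

    @property
    def model_params(self) -> KineticParameters:
        return self.controller_params if self.controller_params is not None else self.params

    def validate(self) -> None:
        if abs(self.batch_duration - self.schedule.t_end) > 1e-9:
            raise ValueError("batch duration must equal the last schedule breakpoint")
        if (
            self.baseline_policy.t0 > self.x0.t + 1e-9
            or self.baseline_policy.t1 < self.batch_duration - 1e-9
        ):
            raise ValueError("baseline policy must span the batch")
        self.control.validate()


@dataclass
class CampaignResult:
    label: str
    trajectory: SimulationTrajectory
    policy: FeedPolicy
    cycles: list[HorizonSolution]
    metrics: dict[str, float]
    params: KineticParameters

    @staticmethod
    def compute_metrics(
        traj: SimulationTrajectory, baseline: "CampaignResult | None" = None
    ) -> dict[str, float]:
        s = traj.final_state
        m = {
            "final_antibody_mass_mg": traj.final_antibody_mass,
            "final_antibody_conc_mg_per_L": s.P,
            "total_glucose_fed_mmol": traj.total_glucose_fed,
            "final_volume_L": s.V,
            "ivcd_1e9cells_h_per_L": traj.ivcd,
        }
        if baseline is not None:
            for key, tag in [
                ("final_antibody_mass_mg", "mass"),
                ("final_antibody_conc_mg_per_L", "conc"),
            ]:
                base = baseline.metrics[key]
                if base > 0:
                    m[f"improvement_{tag}_pct"] = 100.0 * (m[key] - base) / base
        return m


def run_open_loop(
    cc: CampaignConfig, policy: FeedPolicy | None = None, label: str = "open_loop"
) -> CampaignResult:
    """Pure simulation of a policy over the batch, plus metrics."""
    cc.validate()
    policy = cc.baseline_policy if policy is None else policy
    traj = simulate(
        cc.x0, policy, cc.params, cc.batch_duration, output_dt=cc.output_dt
    )
    return CampaignResult(
        label=label,
        trajectory=traj,
        policy=policy,
        cycles=[],
        metrics=CampaignResult.compute_metrics(traj),
        params=cc.params,
    )


def run_closed_loop(cc: CampaignConfig, label: str | None = None) -> CampaignResult:
    """Receding-horizon control of the digital twin (measure -> optimize ->
    implement the first interval -> repeat until batch end)."""
    cc.validate()
    cfg = cc.control
    dt_c = cfg.control_interval
    t, x = cc.x0.t, cc.x0
    segments: list[FeedPolicy] = []
    cycles: list[HorizonSolution] = []
    prev_sol: HorizonSolution | None = None
    prev_glc_feed: float | None = cc.initial_glc_feed
    prev_u: dict[str, float] | None = None
    cycle = 0
    while t < cc.batch_duration - 1e-9:
        if cc.reoptimize == "stage":
            stage_end = next(
                bp for bp in cc.schedule.breakpoints if bp > t + 1e-9
            )
            t_next = min(stage_end, cc.batch_duration)
        else:
            t_next = min(t + dt_c, cc.batch_duration)
        try:
            sol = optimize_horizon(
                x,
                cfg,
                cc.targets,
                cc.schedule,
                cc.model_params,
                feed_concentrations=cc.feed_concentrations,
                prev_glc_feed=prev_glc_feed,
                prev_u=prev_u,
                warm_start=prev_sol.policy if prev_sol is not None else None,
                t_end=cc.batch_duration,
            )
        except Exception as exc:
            raise RuntimeError(
                f"closed loop aborted at cycle {cycle} (t={t:.1f} h): {exc}"
            ) from exc
        segment = sol.policy.restricted(t, t_next)
        segments.append(segment)
        traj = simulate(x, segment, cc.params, t_next, output_dt=cc.output_dt)
        x = traj.final_state
        prev_u = {
            "C_feed_glc": float(np.interp(t_next, sol.policy.knots, sol.policy.C_feed_glc)),
            "F_in": float(np.interp(t_next, sol.policy.knots, sol.policy.F_in)),
            "F_out": float(np.interp(t_next, sol.policy.knots, sol.policy.F_out)),
        }
        prev_glc_feed = prev_u["C_feed_glc"]
        prev_sol = sol
        cycles.append(sol)
        t = t_next
        cycle += 1
    implemented = FeedPolicy.concatenate(segments)
    traj = simulate(
        cc.x0, implemented, cc.params, cc.batch_duration, output_dt=cc.output_dt
    )
    return CampaignResult(
        label=label or f"closed_loop_case{cfg.case}_{dt_c:g}h",
        trajectory=traj,
        policy=implemented,
        cycles=cycles,
        metrics=CampaignResult.compute_metrics(traj),
        params=cc.params,
    )


def compare_campaigns(results: list[CampaignResult]) -> pd.DataFrame:
    """Comparison table across campaigns sharing one twin parameterization.

    The first entry is the reference for percent improvements.
    """
    if len(results) < 2:
        raise ValueError("need at least two campaigns to compare")
    ref = results[0]
    for r in results[1:]:
        if r.params != ref.params:
            raise ValueError(
                f"campaign {r.label!r} uses different twin parameters than {ref.label!r}"
            )
    rows = []
    base_mass = ref.metrics["final_antibody_mass_mg"]
    base_conc = ref.metrics["final_antibody_conc_mg_per_L"]
    for r in results:
        rows.append(
            {
                "label": r.label,
                "final_antibody_mass_mg": r.metrics["final_antibody_mass_mg"],
                "final_antibody_conc_mg_per_L": r.metrics["final_antibody_conc_mg_per_L"],
                "total_glucose_fed_mmol": r.metrics["total_glucose_fed_mmol"],
                "improvement_mass_pct": 100.0
                * (r.metrics["final_antibody_mass_mg"] - base_mass)
                / base_mass,
                "improvement_conc_pct": 100.0
                * (r.metrics["final_antibody_conc_mg_per_L"] - base_conc)
                / base_conc,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def tracking_report(
    result: CampaignResult, targets: StageTargetTable, schedule: StageSchedule
) -> pd.DataFrame:
    """Per-flux tracking diagnostics: integrated squared deviation over the
    batch and mean deviation per culture stage (unit weights)."""
    traj = result.trajectory
    grid = traj.grid
    stages = [schedule.stage_at(float(t)) for t in grid]
    rows = []
    for fid in targets.tracked:
        z = traj.fluxes[fid].to_numpy()
        zt = np.array([targets.target_at(s, fid) for s in stages])
        resid = z - zt
        row = {
            "flux": fid,
            "integrated_sq_dev": float(np.trapezoid(resid**2, grid)),
        }
        for st in STAGES:
            mask = np.array([s == st for s in stages])
            row[f"mean_dev_{st.name}"] = (
                float(np.mean(resid[mask])) if mask.any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("flux")
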