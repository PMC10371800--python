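"""Self-contained illustrative test assets.

A reduced CHO-like toy metabolic network (12 metabolites, 15 reactions)
with five stage-bound sets, a nominal kinetic parameter set, an initial
reactor state and a fixed "original"-style baseline feed policy.  All
values are illustrative — chosen so the toy system reproduces the
qualitative physiology of a fed-batch CHO culture (decreasing growth across
stages, a lactate secretion-to-uptake shift, product flux peaking in early
stationary phase) — and are not estimates from any experimental dataset.

The network is deliberately small enough for brute-force LP verification
by vertex enumeration.

Lumped reactions:

    GLYC     glc -> 2 pyr + 2 atp + 2 nadh        (glycolysis)
    LDH      pyr + nadh <-> lac                   (lactate shuttle, reversible)
    PDH      pyr -> 2 nadh + atp                  (pyruvate oxidation / TCA)
    RESP     nadh -> 2.5 atp                      (oxidative phosphorylation)
    GLNLYS   gln -> akg + nh4 + 0.4 atp           (glutaminolysis)
    TRANSAM  asn + pyr -> ala + oaa + nh4         (asparaginolysis + transamination)
    BIOMASS  0.30 pyr + 0.12 akg + 0.08 oaa + 33 atp + 0.25 nadh ->
    MABSYN   0.18 pyr + 0.10 akg + 0.10 oaa + 25 atp + 0.20 nadh -> mab

The stage bounds tighten glucose/amino-acid uptake and the respiratory
capacity (RESP upper bound) from early exponential to late stationary and
force a small stage-dependent product secretion; the RESP cap is what makes
overflow lactate secretion optimal at high glucose uptake and lactate
consumption optimal once glucose is scarce.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fba import CultureStage, StageBounds, write_stage_bounds
from .kinetics import KineticParameters
from .network import StoichiometricNetwork, load_network
from .twin import FeedPolicy, ReactorState

__all__ = [
    "FIXTURE_VERSION",
    "V_BOUNDS",
    "toy_network_tsv",
    "make_toy_network",
    "make_stage_bounds",
    "make_nominal_params",
    "make_initial_state",
    "make_baseline_policy",
    "make_campaign",
    "feed_concentrations",
    "write_fixture_bundle",
]

FIXTURE_VERSION = "1.0.0"

_NETWORK_ROWS = [
    # id, equation, reversible, exchange, biomass, product
    ("EX_glc", "glc ->", "true", "true", "false", "false"),
    ("EX_gln", "gln ->", "true", "true", "false", "false"),
    ("EX_asn", "asn ->", "true", "true", "false", "false"),
    ("EX_ala", "ala ->", "true", "true", "false", "false"),
    ("EX_lac", "lac ->", "true", "true", "false", "false"),
    ("EX_nh4", "nh4 ->", "true", "true", "false", "false"),
    ("EX_mab", "mab ->", "false", "true", "false", "true"),
    ("GLYC", "glc -> 2 pyr + 2 atp + 2 nadh", "false", "false", "false", "false"),
    ("LDH", "pyr + nadh <-> lac", "true", "false", "false", "false"),
    ("PDH", "pyr -> 2 nadh + 1 atp", "false", "false", "false", "false"),
    ("RESP", "nadh -> 2.5 atp", "false", "false", "false", "false"),
    ("ATPM", "atp ->", "false", "false", "false", "false"),
    ("GLNLYS", "gln -> akg + nh4 + 0.4 atp", "false", "false", "false", "false"),
    ("TRANSAM", "asn + pyr -> ala + oaa + nh4", "false", "false", "false", "false"),
    (
        "BIOMASS",
        "0.30 pyr + 0.12 akg + 0.08 oaa + 20 atp + 0.25 nadh ->",
        "false", "false", "true", "false",
    ),
    (
        "MABSYN",
        "0.18 pyr + 0.10 akg + 0.10 oaa + 16 atp + 0.20 nadh -> mab",
        "false", "false", "false", "false",
    ),
]


def toy_network_tsv() -> str:
    header = "id\tequation\treversible\texchange\tbiomass\tproduct"
    lines = [header] + ["\t".join(row) for row in _NETWORK_ROWS]
    return "\n".join(lines) + "\n"


def make_toy_network() -> StoichiometricNetwork:
    """The toy network, parsed through the regular TSV reader."""
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "toy_network.tsv"
        path.write_text(toy_network_tsv())
        return load_network(path, format="tsv")


# per-stage exchange bounds (uptake expressed as a negative lower bound on
# the exchange flux) and respiratory capacity; order follows CultureStage
_STAGE_TABLE = {
    # stage:            glc_up   gln_up  asn_up  resp_cap  ngam  mab_lb
    "early_exponential": (0.1235, 0.030, 0.030, 0.3095, 0.30, 0.0015),
    "mid_exponential":   (0.0978, 0.024, 0.026, 0.2831, 0.33, 0.0030),
    "late_exponential":  (0.0733, 0.018, 0.020, 0.2630, 0.36, 0.0045),
    "early_stationary":  (0.0444, 0.008, 0.012, 0.2778, 0.50, 0.0060),
    "late_stationary":   (0.0367, 0.004, 0.006, 0.2649, 0.52, 0.0040),
}

#: maximum lactate uptake capacity (all stages), mmol/1e9 cells/h
_LAC_UPTAKE_CAP = 0.08


def make_stage_bounds() -> list[StageBounds]:
    out = []
    for stage in CultureStage:
        glc_up, gln_up, asn_up, resp_cap, ngam, mab_lb = _STAGE_TABLE[stage.name]
        out.append(
            StageBounds(
                stage=stage,
                lb={
                    "EX_glc": -glc_up,
                    "EX_gln": -gln_up,
                    "EX_asn": -asn_up,
                    "EX_lac": -_LAC_UPTAKE_CAP,
                    "EX_ala": 0.0,
                    "EX_nh4": 0.0,
                    "EX_mab": mab_lb,
                    "ATPM": ngam,
                },
                ub={
                    "EX_glc": 0.0,
                    "EX_gln": 0.0,
                    "EX_asn": 0.0,
                    "RESP": resp_cap,
                },
            )
        )
    return out


def make_nominal_params() -> KineticParameters:
    """Nominal twin parameter set (illustrative; see module docstring)."""
    p = KineticParameters()
    p.validate()
    return p


#: working-volume band (L) of the fixture vessel, used by the controller;
#: a narrow band around the 1000 L working volume means sustained feeding
#: must be balanced by outflow, which washes out product — the physical
#: trade-off that makes over-feeding costly
V_BOUNDS: tuple[float, float] = (950.0, 1100.0)


def make_initial_state() -> ReactorState:
    """Pilot-scale inoculation: 1000 L, 0.3e9 viable cells/L, rich medium."""
    return ReactorState(
        t=0.0,
        V=1000.0,
        Xv=0.30,
        Xd=0.01,
        C={"glc": 22.0, "gln": 4.0, "asn": 9.0, "ala": 0.5, "lac": 1.0, "nh4": 1.0},
        P=0.0,
    )


def feed_concentrations() -> dict[str, float]:
    """Fixed feed composition of the non-glucose species (mmol/L)."""
    return {"gln": 25.0, "asn": 12.0, "ala": 0.0, "lac": 0.0, "nh4": 0.0}


def make_baseline_policy(batch_duration: float = 360.0) -> FeedPolicy:
    """"Original"-style open-loop fed-batch feed.

    A conservative constant feed of the kind a historical process sheet
    prescribes: inlet 0.0025 L/min of a 250 mmol/L glucose feed against a
    small constant purge.  Within the manipulated-variable bounds (glucose
    feed 0..1000 mmol/L, inlet 0.001..1 L/min, outlet 0..0.05 L/min) and
    the fixture vessel's working volume band.
    """
    knots = np.linspace(0.0, batch_duration, 6)
    return FeedPolicy(
        knots=knots,
        F_in=np.full(6, 0.15),                                     # L/h
        F_out=np.full(6, 0.03),
        C_feed_glc=np.full(6, 250.0),
        C_feed_other=feed_concentrations(),
    )


def make_campaign(
    case: str = "A",
    control_interval: float = 8.0,
    rate_limit: float | None = None,
    batch_duration: float = 360.0,
    **control_overrides,
):
    """Assemble the full fixture campaign (the package's study conditions).

    Returns a :class:`fedflux.loop.CampaignConfig` wiring the toy network's
    stage targets, the nominal twin, the working-volume band and the
    baseline feed together for a given controller setting.
    """
    from .control import ControlConfig
    from .fba import compute_stage_targets
    from .loop import CampaignConfig, StageSchedule

    net = make_toy_network()
    targets = compute_stage_targets(net, make_stage_bounds())
    schedule = StageSchedule(
        breakpoints=tuple(batch_duration / 360.0 * b for b in (0.0, 72.0, 144.0, 216.0, 288.0, 360.0))
    )
    control = ControlConfig(
        case=case,
        control_interval=control_interval,
        rate_limit=rate_limit,
        v_bounds=V_BOUNDS,
        **control_overrides,
    )
    return CampaignConfig(
        batch_duration=batch_duration,
        schedule=schedule,
        control=control,
        params=make_nominal_params(),
        x0=make_initial_state(),
        baseline_policy=make_baseline_policy(batch_duration),
        targets=targets,
        feed_concentrations=feed_concentrations(),
    )


def write_fixture_bundle(out_dir: str | Path) -> dict[str, str]:
    """Materialize the fixture files; regeneration is byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    net_path = out_dir / "toy_network.tsv"
    net_path.write_text(toy_network_tsv())
    paths["network"] = str(net_path)

    bounds_path = out_dir / "stage_bounds.tsv"
    write_stage_bounds(make_stage_bounds(), bounds_path)
    paths["stage_bounds"] = str(bounds_path)

    p = make_nominal_params()
    x0 = make_initial_state()
    scalar_params = {
        # non-finite values serialized as strings to keep the JSON strict
        k: (v if np.isfinite(v) else "inf")
        for k, v in vars(p).items()
        if not isinstance(v, dict)
    }
    twin_cfg = {
        "version": FIXTURE_VERSION,
        "parameters": scalar_params | {"q_max": p.q_max, "K": p.K},
        "initial_state": {
            "t": x0.t, "V": x0.V, "Xv": x0.Xv, "Xd": x0.Xd, "C": x0.C, "P": x0.P,
        },
        "feed_concentrations": feed_concentrations(),
        "units": {
            "t": "h", "V": "L", "Xv": "1e9 cells/L", "Xd": "1e9 cells/L",
            "C": "mmol/L", "P": "mg/L",
        },
    }
    twin_path = out_dir / "twin_config.json"
    twin_path.write_text(json.dumps(twin_cfg, indent=2, sort_keys=True) + "\n")
    paths["twin_config"] = str(twin_path)

    pol = make_baseline_policy()
    pol_cfg = {
        "knots_h": pol.knots.tolist(),
        "F_in_L_per_h": pol.F_in.tolist(),
        "F_out_L_per_h": pol.F_out.tolist(),
        "C_feed_glc_mmol_per_L": pol.C_feed_glc.tolist(),
        "C_feed_other_mmol_per_L": pol.C_feed_other,
    }
    pol_path = out_dir / "baseline_policy.json"
    pol_path.write_text(json.dumps(pol_cfg, indent=2, sort_keys=True) + "\n")
    paths["baseline_policy"] = str(pol_path)

    manifest = {"version": FIXTURE_VERSION, "files": sorted(paths)}
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = str(man_path)
    return paths
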