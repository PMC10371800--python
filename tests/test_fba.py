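import numpy as np
import pytest
from hypothesis import given, strategies as st

from fedflux.fba import (
    STAGES,
    CultureStage,
    InfeasibleError,
    StageBounds,
    compute_stage_targets,
    solve_fba,
)
from fedflux.network import Metabolite, Reaction, StoichiometricNetwork

from .oracles import vertex_enumeration_lp


def tiny_net():
    """ex_A: -> A; r: A -> (biomass sink)."""
    return StoichiometricNetwork(
        metabolites=[Metabolite(id="A", extracellular=True)],
        reactions=[
            Reaction(id="ex_A", stoichiometry={"A": 1.0}, reversible=True,
                     is_exchange=True),
            Reaction(id="r", stoichiometry={"A": -1.0}, is_biomass=True),
        ],
    )


def test_flux_forced_by_bound():
    net = tiny_net()
    sol = solve_fba(net, StageBounds(stage=STAGES[0], ub={"ex_A": 2.0}))
    assert sol.objective == pytest.approx(2.0)
    assert sol.v["ex_A"] == pytest.approx(2.0)
    assert sol.v["r"] == pytest.approx(2.0)


def test_zero_cone():
    net = tiny_net()
    bounds = StageBounds(stage=STAGES[0], ub={"ex_A": 0.0, "r": 0.0})
    sol = solve_fba(net, bounds)
    assert sol.objective == pytest.approx(0.0)
    assert all(abs(v) < 1e-9 for v in sol.v.values())


def test_conflicting_bounds_raise():
    net = tiny_net()
    with pytest.raises(InfeasibleError, match="ex_A"):
        solve_fba(net, StageBounds(stage=STAGES[0], lb={"ex_A": 3.0}, ub={"ex_A": 2.0}))


@pytest.mark.parametrize("stage", list(CultureStage))
def test_fixture_optimum_matches_vertex_oracle(toy_network, stage_bounds, stage):
    sb = next(b for b in stage_bounds if b.stage == stage)
    sol = solve_fba(toy_network, sb)
    lo, hi = sb.arrays(toy_network)
    c = np.zeros(len(toy_network.reactions))
    c[toy_network.reactions.index(toy_network.biomass_reaction)] = 1.0
    best, _ = vertex_enumeration_lp(toy_network.S, c, lo, hi)
    assert sol.objective == pytest.approx(best, rel=1e-6)


@pytest.mark.parametrize("stage", list(CultureStage))
def test_mass_balance_residual(toy_network, stage_bounds, stage):
    sb = next(b for b in stage_bounds if b.stage == stage)
    v = solve_fba(toy_network, sb).as_array(toy_network)
    resid = np.max(np.abs(toy_network.S @ v))
    assert resid <= 1e-8 * max(1.0, np.max(np.abs(v)))


def test_cobra_cross_check(toy_network, stage_bounds):
    """Independent constraint-based solver agrees on the biomass optimum."""
    cobra = pytest.importorskip("cobra")
    from cobra import Metabolite as CM, Model, Reaction as CR

    sb = stage_bounds[0]
    lo, hi = sb.arrays(toy_network)
    model = Model("toy")
    mets = {m.id: CM(m.id) for m in toy_network.metabolites}
    for j, rxn in enumerate(toy_network.reactions):
        cr = CR(rxn.id)
        cr.lower_bound, cr.upper_bound = lo[j], hi[j]
        model.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
    model.objective = "BIOMASS"
    ours = solve_fba(toy_network, sb).objective
    theirs = model.optimize().objective_value
    assert ours == pytest.approx(theirs, rel=1e-6)


def test_bound_relaxation_never_decreases_optimum(toy_network, stage_bounds):
    rng = np.random.default_rng(0)
    sb = stage_bounds[0]
    base = solve_fba(toy_network, sb, minimize_norm=False).objective
    for _ in range(10):
        relaxed = StageBounds(stage=sb.stage, lb=dict(sb.lb), ub=dict(sb.ub))
        for rid in rng.choice(list(relaxed.ub), size=2, replace=False):
            relaxed.ub[rid] = relaxed.ub[rid] + float(rng.uniform(0.0, 0.1))
        new = solve_fba(toy_network, relaxed, minimize_norm=False).objective
        assert new >= base - 1e-9


def test_stage_targets_deterministic(toy_network, stage_bounds):
    t1 = compute_stage_targets(toy_network, stage_bounds)
    t2 = compute_stage_targets(toy_network, stage_bounds)
    assert t1.targets == t2.targets  # bitwise identical values


def test_identical_bounds_give_identical_rows(toy_network, stage_bounds):
    same = [
        StageBounds(stage=s, lb=dict(stage_bounds[0].lb), ub=dict(stage_bounds[0].ub))
        for s in STAGES
    ]
    table = compute_stage_targets(toy_network, same)
    rows = [table.targets[s] for s in STAGES]
    assert all(r == rows[0] for r in rows)


def test_biomass_targets_strictly_decreasing(stage_targets):
    seq = [stage_targets.target_at(s, "biomass") for s in STAGES]
    assert all(a > b for a, b in zip(seq, seq[1:]))


def test_lactate_shift_in_targets(stage_targets):
    lac = [stage_targets.target_at(s, "lac") for s in STAGES]
    assert lac[0] > 0 and lac[1] > 0 and lac[2] > 0          # secretion
    assert lac[3] < 0 and lac[4] < 0                         # uptake


def test_product_target_peaks_early_stationary(stage_targets):
    prod = {s: stage_targets.target_at(s, "product") for s in STAGES}
    assert max(prod, key=prod.get) == CultureStage.early_stationary


def test_glucose_targets_are_uptake(stage_targets):
    assert all(stage_targets.target_at(s, "glc") < 0 for s in STAGES)


@given(scale=st.floats(min_value=0.1, max_value=2.0))
def test_objective_scales_with_glucose_cap(toy_network, stage_bounds, scale):
    """Tightening the dominant substrate cap can only reduce the optimum."""
    sb = stage_bounds[0]
    scaled = StageBounds(stage=sb.stage, lb=dict(sb.lb), ub=dict(sb.ub))
    scaled.lb["EX_glc"] = sb.lb["EX_glc"] * scale
    base = solve_fba(toy_network, sb, minimize_norm=False).objective
    new = solve_fba(toy_network, scaled, minimize_norm=False).objective
    if scale <= 1.0:
        assert new <= base + 1e-9
    else:
        assert new >= base - 1e-9
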