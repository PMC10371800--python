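"""Stoichiometric network container and readers.

A :class:`StoichiometricNetwork` is the static, intracellular half of the
control framework: a metabolite-by-reaction matrix ``S`` of signed
coefficients together with reversibility flags and role tags (exchange,
biomass, product).  Networks are read either from a small tab-separated
dialect (one reaction per row, an equation string such as ``"A + 2 B -> C"``)
or from SBML Level 3 via cobra.

Sign conventions follow COBRA: an exchange reaction for species ``X`` is
written ``X ->`` (coefficient -1), so positive flux is secretion and negative
flux is uptake.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricNetwork",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_network",
    "parse_equation",
    "validate_network",
]


class NetworkFormatError(ValueError):
    """A network file could not be parsed; the message names the line."""


class NetworkValidationError(ValueError):
    """A parsed network violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    extracellular: bool = False


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    is_exchange: bool = False
    is_biomass: bool = False
    is_product: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not np.isfinite(coef) or coef == 0.0:
                raise NetworkValidationError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be finite and nonzero"
                )


@dataclass
class StoichiometricNetwork:
    """Ordered metabolites/reactions plus the implied dense S matrix."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    _S: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def S(self) -> np.ndarray:
        if self._S is None:
            idx = {m.id: i for i, m in enumerate(self.metabolites)}
            S = np.zeros((len(self.metabolites), len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for met, coef in rxn.stoichiometry.items():
                    S[idx[met], j] = coef
            self._S = S
        return self._S

    @property
    def biomass_reaction(self) -> Reaction:
        for rxn in self.reactions:
            if rxn.is_biomass:
                return rxn
        raise NetworkValidationError("network has no biomass reaction")

    @property
    def product_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_product]

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """The unique exchange reaction touching a metabolite, if any."""
        hits = [
            r
            for r in self.reactions
            if r.is_exchange and metabolite_id in r.stoichiometry
        ]
        if len(hits) > 1:
            raise NetworkValidationError(
                f"metabolite {metabolite_id!r} has {len(hits)} exchange reactions"
            )
        return hits[0] if hits else None

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


_ARROWS = ("<->", "<=>", "-->", "->", "=>")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A + 2 B -> C"`` into a stoichiometry map and reversibility.

    An empty side denotes the system boundary (exchange/sink reactions).
    """
    arrow = None
    for a in ("<->", "<=>"):
        if a in eq:
            arrow, reversible = a, True
            break
    else:
        for a in ("-->", "->", "=>"):
            if a in eq:
                arrow, reversible = a, False
                break
    if arrow is None:
        raise NetworkFormatError(f"no reaction arrow in equation {eq!r}")
    lhs, rhs = (side.strip() for side in eq.split(arrow, 1))
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkFormatError(f"empty term in equation {eq!r}")
            m = re.fullmatch(r"(?:(\d+(?:\.\d+)?)\s+)?(\S+)", term)
            if m is None:
                raise NetworkFormatError(f"cannot parse term {term!r} in {eq!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    # cancel species appearing on both sides with equal coefficients
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise NetworkFormatError(f"equation {eq!r} cancels to nothing")
    return stoich, reversible


_TSV_COLUMNS = ["id", "equation", "reversible", "exchange", "biomass", "product"]
_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _parse_flag(token: str, line_no: int, col: str) -> bool:
    token = token.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise NetworkFormatError(f"line {line_no}: bad boolean {token!r} in column {col!r}")


def _load_tsv(path: Path) -> StoichiometricNetwork:
    lines = path.read_text().splitlines()
    if not lines:
        raise NetworkFormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split("\t")]
    if header != _TSV_COLUMNS:
        raise NetworkFormatError(
            f"{path}: header must be {_TSV_COLUMNS}, got {header}"
        )
    reactions: list[Reaction] = []
    met_order: list[str] = []
    extracellular: set[str] = set()
    for line_no, raw in enumerate(lines[1:], start=2):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cells = raw.split("\t")
        if len(cells) != len(_TSV_COLUMNS):
            raise NetworkFormatError(
                f"line {line_no}: expected {len(_TSV_COLUMNS)} columns, got {len(cells)}"
            )
        rid = cells[0].strip()
        if not rid:
            raise NetworkFormatError(f"line {line_no}: empty reaction id")
        try:
            stoich, rev_from_eq = parse_equation(cells[1])
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"line {line_no}: {exc}") from exc
        reversible = _parse_flag(cells[2], line_no, "reversible") or rev_from_eq
        is_exchange = _parse_flag(cells[3], line_no, "exchange")
        is_biomass = _parse_flag(cells[4], line_no, "biomass")
        is_product = _parse_flag(cells[5], line_no, "product")
        for met in stoich:
            if met not in met_order:
                met_order.append(met)
            if is_exchange:
                extracellular.add(met)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                is_exchange=is_exchange,
                is_biomass=is_biomass,
                is_product=is_product,
            )
        )
    metabolites = [
        Metabolite(id=m, extracellular=m in extracellular) for m in met_order
    ]
    net = StoichiometricNetwork(metabolites=metabolites, reactions=reactions)
    findings = validate_network(net)
    hard = [f for f in findings if f.startswith(("duplicate", "missing biomass"))]
    if hard:
        raise NetworkValidationError("; ".join(hard))
    return net


def _load_sbml(path: Path) -> StoichiometricNetwork:
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    exchange_ids = {r.id for r in model.exchanges}
    objective_ids = {
        r.id for r in model.reactions if r.objective_coefficient != 0
    }
    boundary_mets = {
        m.id for r in model.reactions if r.id in exchange_ids for m in r.metabolites
    }
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", extracellular=m.id in boundary_mets)
        for m in model.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            reversible=r.reversibility,
            is_exchange=r.id in exchange_ids,
            is_biomass=r.id in objective_ids or "biomass" in r.id.lower(),
            is_product=False,
        )
        for r in model.reactions
    ]
    return StoichiometricNetwork(metabolites=metabolites, reactions=reactions)


def load_network(path: str | Path, format: str | None = None) -> StoichiometricNetwork:
    """Read a network from TSV or SBML; order follows the file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tsv"
    if format == "tsv":
        return _load_tsv(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def validate_network(net: StoichiometricNetwork) -> list[str]:
    """Structural findings; empty list means every invariant holds."""
    findings: list[str] = []
    seen_m: set[str] = set()
    for m in net.metabolites:
        if m.id in seen_m:
            findings.append(f"duplicate metabolite id {m.id!r}")
        seen_m.add(m.id)
    seen_r: set[str] = set()
    for r in net.reactions:
        if r.id in seen_r:
            findings.append(f"duplicate reaction id {r.id!r}")
        seen_r.add(r.id)
        for met in r.stoichiometry:
            if met not in seen_m:
                findings.append(
                    f"reaction {r.id!r} references unknown metabolite {met!r}"
                )
    n_biomass = sum(r.is_biomass for r in net.reactions)
    if n_biomass == 0:
        findings.append("missing biomass reaction")
    elif n_biomass > 1:
        findings.append(f"{n_biomass} biomass reactions, expected exactly 1")

    # orphan / dead-end metabolites
    producers: dict[str, int] = {m.id: 0 for m in net.metabolites}
    consumers: dict[str, int] = {m.id: 0 for m in net.metabolites}
    touched: set[str] = set()
    for r in net.reactions:
        for met, coef in r.stoichiometry.items():
            if met not in producers:
                continue
            touched.add(met)
            if coef > 0 or r.reversible:
                producers[met] += 1
            if coef < 0 or r.reversible:
                consumers[met] += 1
    for m in net.metabolites:
        if m.id not in touched:
            findings.append(f"orphan metabolite {m.id!r} (appears in no reaction)")
        elif producers[m.id] == 0 or consumers[m.id] == 0:
            findings.append(
                f"dead-end metabolite {m.id!r} "
                f"(producers={producers[m.id]}, consumers={consumers[m.id]})"
            )

    # at most one exchange reaction per extracellular species
    ex_count: dict[str, list[str]] = {}
    for r in net.reactions:
        if r.is_exchange:
            for met in r.stoichiometry:
                ex_count.setdefault(met, []).append(r.id)
    for met, rids in ex_count.items():
        if len(rids) > 1:
            findings.append(
                f"duplicate exchange for metabolite {met!r}: {sorted(rids)}"
            )
    return findings
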