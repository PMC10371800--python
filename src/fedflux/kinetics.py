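"""Monod-type cell culture kinetics.

Rate laws for the fed-batch digital twin: multiplicative Monod limitation of
growth by glucose, glutamine and asparagine with lactate and ammonia
inhibition; a basal death rate with a linear ammonia term; specific
uptake/secretion rates per metabolite; and Luedeking-Piret antibody
production (growth-associated term ``alpha*mu`` plus a constant ``beta``).

The lactate shift — secretion proportional to glycolytic flux at high
glucose, Monod consumption at low glucose — is blended smoothly across a
glucose threshold so the right-hand side stays differentiable for the
optimizer.

Units: h, L, mmol/L, 1e9 cells/L, mg/L.  Specific rates are mmol per 1e9
cells per hour in the exchange sign convention (secretion > 0, uptake < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticParameters", "growth_rate", "death_rate", "specific_rates"]

GLC, GLN, ASN, ALA, LAC, AMM = "glc", "gln", "asn", "ala", "lac", "nh4"


@dataclass
class KineticParameters:
    """Kinetic parameter set for the digital twin.

    The shipped nominal fixture values are illustrative (chosen to produce a
    realistic-looking CHO fed-batch at reduced scale), not estimates from any
    experimental dataset.  A set instantiated from the defaults below has 26
    free scalar parameters (see :meth:`n_parameters`).
    """

    mu_max: float = 0.045          # h^-1
    K_glc: float = 0.15            # mmol/L
    KI_glc: float = float("inf")   # mmol/L substrate (osmotic) inhibition; inf = off
    K_gln: float = 0.05            # mmol/L
    K_asn: float = 0.10            # mmol/L
    KI_lac: float = 15.0           # mmol/L
    KI_amm: float = 8.0            # mmol/L
    kd_0: float = 0.0015           # h^-1
    kd_amm: float = 0.0012         # h^-1 per mmol/L
    # glucose uptake: growth-linked + maintenance
    Y_xg: float = 0.32             # 1e9 cells per mmol glucose
    m_glc: float = 0.015           # mmol/1e9 cells/h maintenance cap
    K_mglc: float = 0.3            # mmol/L
    # lactate
    Y_lg: float = 1.4              # mmol lactate per mmol glucose (overflow)
    q_lac_max: float = 0.15        # mmol/1e9 cells/h max consumption
    K_lac: float = 3.0             # mmol/L
    lac_switch: float = 2.0        # mmol/L glucose threshold for the shift
    lac_switch_width: float = 0.5  # mmol/L sigmoid width
    # amino-acid uptake (Monod): metabolite -> (q_max, K)
    q_max: dict[str, float] = field(
        default_factory=lambda: {GLN: 0.0017, ASN: 0.0013}
    )
    K: dict[str, float] = field(default_factory=lambda: {GLN: 0.2, ASN: 0.3})
    # yield-linked secondary rates
    Y_amm_gln: float = 0.8         # mmol ammonia per mmol glutamine
    Y_amm_asn: float = 0.7         # mmol ammonia per mmol asparagine
    Y_ala_asn: float = 0.6         # mmol alanine per mmol asparagine
    # Luedeking-Piret antibody production
    alpha: float = 8.0             # mg per 1e9 cells
    beta: float = 0.10             # mg per 1e9 cells per h

    def validate(self) -> None:
        pos = {
            "mu_max": self.mu_max,
            "K_glc": self.K_glc,
            "K_gln": self.K_gln,
            "K_asn": self.K_asn,
            "KI_lac": self.KI_lac,
            "KI_amm": self.KI_amm,
            "Y_xg": self.Y_xg,
            "K_mglc": self.K_mglc,
            "K_lac": self.K_lac,
            "lac_switch_width": self.lac_switch_width,
        }
        for name, val in pos.items():
            if not val > 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        for m, k in self.K.items():
            if not k > 0:
                raise ValueError(f"K[{m!r}] must be > 0")
        if self.kd_0 < 0 or self.kd_amm < 0:
            raise ValueError("death-rate parameters must be nonnegative")

    def n_parameters(self) -> int:
        """Number of free scalar parameters in this set."""
        scalars = 22  # the non-dict fields above
        return scalars + len(self.q_max) + len(self.K)


def _conc(C: dict[str, float], key: str) -> float:
    # clip at 0: rates are evaluated on the physical (nonnegative) part
    return max(float(C.get(key, 0.0)), 0.0)


def growth_rate(C: dict[str, float], p: KineticParameters) -> float:
    """Specific growth rate mu (h^-1).

    mu = mu_max * glc/(K_glc+glc) * KI_glc/(KI_glc+glc)
               * gln/(K_gln+gln) * asn/(K_asn+asn)
               * KI_lac/(KI_lac+lac) * KI_amm/(KI_amm+amm)

    The Haldane-type glucose term models hyperosmotic stress at very high
    glucose; set ``KI_glc = math.inf`` to recover plain Monod limitation.
    """
    glc, gln, asn = _conc(C, GLC), _conc(C, GLN), _conc(C, ASN)
    lac, amm = _conc(C, LAC), _conc(C, AMM)
    ki_glc = 1.0 if np.isinf(p.KI_glc) else p.KI_glc / (p.KI_glc + glc)
    return (
        p.mu_max
        * glc / (p.K_glc + glc)
        * ki_glc
        * gln / (p.K_gln + gln)
        * asn / (p.K_asn + asn)
        * p.KI_lac / (p.KI_lac + lac)
        * p.KI_amm / (p.KI_amm + amm)
    )


def death_rate(C: dict[str, float], p: KineticParameters) -> float:
    """Specific death rate mu_d = kd_0 + kd_amm * [ammonia]."""
    return p.kd_0 + p.kd_amm * _conc(C, AMM)


def lactate_blend(glc: float, p: KineticParameters) -> float:
    """Smooth 0..1 weight of the secretion branch of the lactate shift."""
    return 1.0 / (1.0 + np.exp(-(glc - p.lac_switch) / p.lac_switch_width))


def specific_rates(C: dict[str, float], p: KineticParameters) -> dict[str, float]:
    """Specific exchange rates q_i (mmol/1e9 cells/h, secretion > 0).

    Glucose: q_glc = mu/Y_xg + m_glc*glc/(K_mglc+glc) (uptake, reported
    negative).  Lactate: overflow secretion Y_lg*q_glc above the glucose
    switch, Monod consumption below it, sigmoid-blended.  Ammonia and alanine
    are yield-linked to glutamine/asparagine uptake.
    """
    mu = growth_rate(C, p)
    glc = _conc(C, GLC)
    q_glc_up = mu / p.Y_xg + p.m_glc * glc / (p.K_mglc + glc)
    if glc == 0.0:
        q_glc_up = 0.0

    q_aa_up = {}
    for met in p.q_max:
        c = _conc(C, met)
        q_aa_up[met] = p.q_max[met] * c / (p.K[met] + c)

    w = lactate_blend(glc, p)
    lac = _conc(C, LAC)
    q_lac = w * p.Y_lg * q_glc_up - (1.0 - w) * p.q_lac_max * lac / (p.K_lac + lac)

    q_amm = p.Y_amm_gln * q_aa_up[GLN] + p.Y_amm_asn * q_aa_up[ASN]
    q_ala = p.Y_ala_asn * q_aa_up[ASN]

    return {
        GLC: -q_glc_up,
        GLN: -q_aa_up[GLN],
        ASN: -q_aa_up[ASN],
        LAC: q_lac,
        AMM: q_amm,
        ALA: q_ala,
    }
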