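"""Syntrophic coupling: cancel a shared intermediate between two partial reactions.

In obligate syntrophy a donor reaction (e.g. beta-oxidation of oleate,
endergonic at standard state) is only feasible because a partner reaction
consumes its product intermediate (here H2) and keeps it at a low level.
This module builds the overall two-partner reaction by exact cancellation of
the intermediate, and computes the intermediate level at which the donor
reaction crosses dG = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .chem import CompoundTable
from .reactions import (
    Reaction,
    ThermoConditions,
    combine,
    delta_g_standard_prime,
)

__all__ = ["CouplingResult", "CouplingError", "couple_on_intermediate", "critical_intermediate_level"]


class CouplingError(ValueError):
    """The intermediate is missing from one reaction or has the wrong sign."""


@dataclass(frozen=True)
class CouplingResult:
    """Overall reaction of a donor/sink pair with the H2-cancelling multiplier.

    ``sink_multiplier`` is the number of formula units of the sink reaction
    run per formula unit of the donor; the intermediate has coefficient zero
    in ``overall``.
    """

    sink_multiplier: Fraction
    overall: Reaction
    dg_prime_overall: float | None = None


def couple_on_intermediate(
    donor: Reaction,
    sink: Reaction,
    intermediate: str,
    *,
    dg_donor: float | None = None,
    dg_sink: float | None = None,
    table: CompoundTable | None = None,
    cond: ThermoConditions | None = None,
) -> CouplingResult:
    """Combine donor and sink so the shared intermediate cancels exactly.

    The multiplier is ``nu_int(donor) / |nu_int(sink)|``; the overall reaction
    is normalised to one formula unit of the donor.  The overall dG0' is the
    matching linear combination of ``dg_donor``/``dg_sink`` when both are
    given, or is computed from formation energies when a ``table`` is given;
    otherwise it is ``None``.
    """
    nu_donor = donor.coefficient(intermediate)
    nu_sink = sink.coefficient(intermediate)
    if nu_donor <= 0:
        raise CouplingError(f"{intermediate!r} is not a product of the donor reaction")
    if nu_sink >= 0:
        raise CouplingError(f"{intermediate!r} is not a reactant of the sink reaction")
    multiplier = nu_donor / -nu_sink
    labels = (donor.label or "donor", sink.label or "sink")
    overall = combine(
        [(donor, Fraction(1)), (sink, multiplier)],
        label=f"{labels[0]} + {multiplier} x {labels[1]} (via {intermediate})",
    )
    dg: float | None = None
    if dg_donor is not None and dg_sink is not None:
        dg = float(dg_donor) + float(multiplier) * float(dg_sink)
    elif table is not None:
        dg = delta_g_standard_prime(overall, table, cond)
    return CouplingResult(multiplier, overall, dg)


def critical_intermediate_level(
    donor: Reaction,
    table: CompoundTable,
    cond: ThermoConditions | None = None,
    intermediate: str = "H2",
    fixed_activities: Mapping[str, float] | None = None,
) -> float:
    """Intermediate activity (standard-state units) at which dG of the donor is 0.

    Closed-form inversion of ``dG0' + R*T*(sum_fixed nu*ln a + nu_int*ln a_int) = 0``.
    For an H2-producing donor this is the ceiling above which the reaction is
    endergonic; for an H2-consuming sink, the floor below which it stalls.
    """
    cond = cond if cond is not None else ThermoConditions()
    key = table.resolve(intermediate).id
    nu_int = donor.coefficient(key)
    if nu_int == 0:
        raise CouplingError(f"{intermediate!r} does not appear in the donor reaction")
    dg0 = delta_g_standard_prime(donor, table, cond)
    fixed_sum = 0.0
    for sp, a in (fixed_activities or {}).items():
        if a <= 0:
            raise ValueError(f"activity of {sp!r} must be positive, got {a}")
        cid = table.resolve(sp).id
        if cid == key:
            raise ValueError("the intermediate cannot appear in fixed_activities")
        fixed_sum += float(donor.coefficient(cid)) * math.log(a)
    ln_a = -(dg0 / cond.rt_kj + fixed_sum) / float(nu_int)
    return math.exp(ln_a)
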