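"""Theoretical yields, product recoveries and conversion-fraction bookkeeping.

Yields follow directly from the stoichiometry of an overall reaction;
recoveries compare measured final concentrations with those predictions, per
product (molar) and aggregated on carbon and electron-equivalent bases.  The
aggregate recoveries are a bookkeeping extension beyond per-product molar
accounting and are reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chem import CompoundTable, degree_of_reduction

__all__ = [
    "YieldPrediction",
    "RecoveryReport",
    "predict_yields",
    "recovery",
    "conversion_fraction",
]


@dataclass(frozen=True)
class YieldPrediction:
    """Stoichiometric amounts (mM) for a given dose of the basis substrate."""

    substrate: str
    substrate_mM: float
    co_substrates: Mapping[str, float]
    products: Mapping[str, float]


@dataclass(frozen=True)
class RecoveryReport:
    """Measured-over-predicted percentages.

    ``per_product`` is molar per species; ``carbon_recovery`` and
    ``electron_recovery`` aggregate the measured product channels by carbon
    atoms and by degree-of-reduction electron equivalents.  Species measured
    above a zero prediction are listed in ``flagged`` instead of divided.
    """

    per_product: Mapping[str, float]
    carbon_recovery: float | None
    electron_recovery: float | None
    flagged: tuple[str, ...] = ()


def predict_yields(overall, substrate: str, amount_mM: float) -> YieldPrediction:
    """Scale the overall reaction to ``amount_mM`` of ``substrate``.

    Every product amount is ``amount * nu_product / |nu_substrate|``;
    co-substrate requirements likewise.  ``substrate`` must be a reactant.
    """
    nu_s = overall.coefficient(substrate)
    if nu_s >= 0:
        raise ValueError(f"{substrate!r} is not a reactant of the overall reaction")
    if amount_mM < 0:
        raise ValueError("substrate amount must be nonnegative")
    scale = amount_mM / float(-nu_s)
    products = {sp: float(nu) * scale for sp, nu in overall.stoich.items() if nu > 0}
    co = {
        sp: float(-nu) * scale
        for sp, nu in overall.stoich.items()
        if nu < 0 and sp != substrate
    }
    return YieldPrediction(substrate, amount_mM, co, products)


def recovery(
    measured_final: Mapping[str, float],
    prediction: YieldPrediction,
    table: CompoundTable,
) -> RecoveryReport:
    """Compare measured final concentrations (mM) against a yield prediction.

    Measured keys must belong to the prediction's products or substrates.
    Substrate channels carry no product recovery; product channels yield
    ``100 * measured / predicted`` plus carbon/electron aggregates.
    """
    allowed = (
        set(prediction.products)
        | set(prediction.co_substrates)
        | {prediction.substrate}
    )
    unknown = sorted(set(measured_final) - allowed)
    if unknown:
        raise KeyError(f"measured species absent from the reaction network: {unknown}")
    per: dict[str, float] = {}
    flagged: list[str] = []
    m_carbon = p_carbon = m_elec = p_elec = 0.0
    for sp, m in measured_final.items():
        if m < 0:
            raise ValueError(f"negative measured concentration for {sp!r}")
        if sp not in prediction.products:
            continue
        p = prediction.products[sp]
        if p == 0:
            if m > 0:
                flagged.append(sp)
            continue
        per[sp] = 100.0 * (m / p)  # ratio first: identical inputs give exactly 100.0
        comp = table.resolve(sp).composition
        n_c = float(comp.count("C"))
        gamma = float(degree_of_reduction(comp))
        m_carbon += m * n_c
        p_carbon += p * n_c
        m_elec += m * gamma
        p_elec += p * gamma
    carbon = 100.0 * (m_carbon / p_carbon) if p_carbon else None
    electron = 100.0 * (m_elec / p_elec) if p_elec else None
    return RecoveryReport(per, carbon, electron, tuple(flagged))


def conversion_fraction(observed_product_mM: float, initial_substrate_mM: float) -> float:
    """Percentage of the initial substrate accounted for by a 1:1 molar product.

    E.g. 3 mM free bromide from a 20 mM bromoethanesulfonate dose -> 15 %.
    """
    if initial_substrate_mM <= 0:
        raise ValueError("initial substrate amount must be positive")
    if observed_product_mM < 0:
        raise ValueError("observed product amount must be nonnegative")
    return 100.0 * observed_product_mM / initial_substrate_mM
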