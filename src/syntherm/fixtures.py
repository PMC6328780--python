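"""Bundled reference data: compound table, reaction network, reference energies.

The package ships a small curated network for anaerobic oleate degradation
coupled to methanogenesis or to isethionate desulfonation:

* ``compounds.tsv`` - formation energies (literature constants; oleate and
  isethionate back-calibrated, see below),
* ``reactions.rxn`` - the eleven reactions, labelled r1..r9 (r4 splits into
  r4.1 sulfite oxidation and r4.2 sulfite reduction),
* ``reference_dg.tsv`` - reference dG0' per reaction at pH 7 / 25 degC.

Oleate and isethionate have no tabulated formation energies; on load they
are solved algebraically so that r1 (beta-oxidation) and r3 (desulfonation)
reproduce their reference dG0' exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem import CompoundTable, calibrate_formation_energy
from .reactions import Reaction, parse_reaction

__all__ = [
    "ReactionNetwork",
    "CALIBRATION_TARGETS",
    "COMPOSITE_RELATIONS",
    "PRIMITIVE_LABELS",
    "load_network",
    "load_reaction_file",
]

#: compound id -> reaction label whose reference dG0' pins its formation energy
CALIBRATION_TARGETS: dict[str, str] = {"oleate": "r1", "isethionate": "r3"}

#: composite label -> linear combination of component labels (exact rationals)
COMPOSITE_RELATIONS: dict[str, dict[str, Fraction]] = {
    "r4": {"r4.1": Fraction(3), "r4.2": Fraction(1)},
    "r5": {"r4.1": Fraction(-1), "r4.2": Fraction(1)},
    "r6": {"r3": Fraction(2), "r4.1": Fraction(1), "r4.2": Fraction(1)},
    "r7": {"r3": Fraction(1), "r4.2": Fraction(1)},
    "r8": {"r1": Fraction(1), "r7": Fraction(15, 2)},
    "r9": {"r1": Fraction(1), "r2": Fraction(15, 4)},
}

#: reactions whose dG0' is computed directly from literature formation energies
PRIMITIVE_LABELS: tuple[str, ...] = ("r2", "r4", "r4.1", "r4.2", "r5")


@dataclass(frozen=True)
class ReactionNetwork:
    """The bundled network: compounds, reactions and reference energies."""

    table: CompoundTable
    reactions: dict[str, Reaction]
    reference_dg: dict[str, float]
    descriptions: dict[str, str]


def _data_path(name: str):
    return resources.files("syntherm") / "data" / name


def load_reaction_file(path, table: CompoundTable | None = None) -> dict[str, Reaction]:
    """Parse a ``.rxn`` file: one ``"label: LHS -> RHS"`` per line, '#' comments."""
    reactions: dict[str, Reaction] = {}
    text = Path(path).read_text(encoding="utf-8") if not hasattr(path, "read_text") else path.read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'label: equation', got {raw!r}")
        label, equation = line.split(":", 1)
        label = label.strip()
        if label in reactions:
            raise ValueError(f"line {lineno}: duplicate reaction label {label!r}")
        reactions[label] = parse_reaction(equation, table=table, label=label)
    return reactions


def load_network(
    calibrate: bool = True,
    compounds=None,
    reactions=None,
    reference=None,
) -> ReactionNetwork:
    """Load the bundled network (or override any of the three fixture files).

    With ``calibrate=True`` (default) the formation energies of oleate and
    isethionate are back-derived from the reference dG0' of r1 and r3.
    """
    compounds_src = compounds if compounds is not None else _data_path("compounds.tsv")
    reactions_src = reactions if reactions is not None else _data_path("reactions.rxn")
    reference_src = reference if reference is not None else _data_path("reference_dg.tsv")

    table = CompoundTable.from_tsv(compounds_src)
    rxns = load_reaction_file(reactions_src, table=table)
    ref_df = pd.read_csv(reference_src, sep="\t", comment="#")
    reference_dg = {str(r.label): float(r.dg0_prime_kJ) for r in ref_df.itertuples(index=False)}
    descriptions = {str(r.label): str(r.description) for r in ref_df.itertuples(index=False)}
    if calibrate:
        for cid, lbl in CALIBRATION_TARGETS.items():
            value = calibrate_formation_energy(rxns[lbl], table, reference_dg[lbl])
            table.set_dgf(cid, value, source=f"calibrated from {lbl}")
    return ReactionNetwork(table, rxns, reference_dg, descriptions)
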