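"""Chemical species registry: formulas, electron equivalents, formation energies.

Conventions
-----------
* Elemental compositions and charges are exact rationals
  (:class:`fractions.Fraction`), so linear combinations of reactions cancel
  without any numerical tolerance.
* The degree of reduction gamma counts electron equivalents relative to the
  reference couple CO2 / H2O / H+ / SO4^2- / NH4+ / Br-::

      gamma = 4 nC + nH - 2 nO + 6 nS - 3 nN - nBr - charge

  Every reference species has gamma = 0, and gamma is conserved by any
  element- and charge-balanced reaction, which makes it a cheap independent
  check on fermentation stoichiometries.
* Standard Gibbs energies of formation are kJ/mol at 25 degC with solutes at
  1 M and gases at 1e5 Pa.  The proton never carries a formation energy: pH
  enters reaction energetics only through the transformed-state correction
  term (see :mod:`syntherm.reactions`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import pandas as pd

__all__ = [
    "ElementalComposition",
    "Compound",
    "CompoundTable",
    "FormulaError",
    "UnknownCompoundError",
    "CalibrationError",
    "parse_formula",
    "compose_formula",
    "degree_of_reduction",
    "calibrate_formation_energy",
    "PHASES",
]

Rational = Union[int, Fraction]

PHASES = ("aqueous", "gas", "liquid-water")

_ELEMENT_SYMBOLS = frozenset(
    """
    H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I
    Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt
    Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu
    """.split()
)

# Electron equivalents per atom, relative to CO2/H2O/H+/SO4^2-/NH4+/Br-.
_GAMMA_WEIGHTS: dict[str, Fraction] = {
    "C": Fraction(4),
    "H": Fraction(1),
    "O": Fraction(-2),
    "S": Fraction(6),
    "N": Fraction(-3),
    "Br": Fraction(-1),
}


class FormulaError(ValueError):
    """A species formula string could not be parsed."""


class UnknownCompoundError(KeyError):
    """A compound id (or formula) is not present in the table."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class CalibrationError(ValueError):
    """Formation-energy back-calibration is ill-posed for this reaction."""


@dataclass(frozen=True)
class ElementalComposition:
    """Exact element counts plus net charge of one chemical species."""

    counts: Mapping[str, Fraction]
    charge: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        clean: dict[str, Fraction] = {}
        for el, n in self.counts.items():
            if el not in _ELEMENT_SYMBOLS:
                raise FormulaError(f"unknown element symbol {el!r}")
            n = Fraction(n)
            if n < 0:
                raise FormulaError(f"negative count for element {el}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)
        object.__setattr__(self, "charge", Fraction(self.charge))

    def count(self, element: str) -> Fraction:
        return self.counts.get(element, Fraction(0))

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, Fraction(0)) + n
        return ElementalComposition(merged, self.charge + other.charge)

    def __rmul__(self, k: Rational) -> "ElementalComposition":
        k = Fraction(k)
        return ElementalComposition(
            {el: k * n for el, n in self.counts.items()}, k * self.charge
        )

    def __str__(self) -> str:
        return compose_formula(self)


# Tolerant reader: unicode minus/superscripts and the underscore-subscript
# markup that shows up in copy-pasted equations are normalised away.
_SUPERSCRIPTS = str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹⁺⁻", "0123456789+-")
_DASHES = ("−", "–", "‐")

# Charge suffix dialects, in decreasing specificity:
#   ^2-  ^-  ^2-^  ^-^   (caret-marked, magnitude before sign)
#   -2   +2            (sign before magnitude)
#   -    +             (bare sign, magnitude 1)
# Digits immediately before a bare trailing sign ("C2H3O2-") always belong to
# the formula, never to the charge; an explicit caret is required to write a
# multiple charge with the magnitude first.
_CHARGE_RE = re.compile(
    r"""(?: \^(?P<n1>\d+(?:/\d+)?)?(?P<s1>[+-])\^?
          | (?P<s2>[+-])(?P<n2>\d+(?:/\d+)?)\^?
          | (?P<s3>[+-])
        )$""",
    re.X,
)

_ELEMENT_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d+(?:/\d+)?)?")


def _normalise(text: str) -> str:
    t = text.strip().translate(_SUPERSCRIPTS)
    for dash in _DASHES:
        t = t.replace(dash, "-")
    return t.replace("_", "")


def parse_formula(text: str) -> ElementalComposition:
    """Parse ``"C2H3O2-"``, ``"SO3^2-"``, ``"C_18_H_33_O_2_^-^"`` and friends.

    Raises :class:`FormulaError` for unknown element symbols or malformed
    charge suffixes.  Parsing is invertible via :func:`compose_formula` up to
    canonical (Hill) element ordering.
    """
    t = _normalise(text)
    if not t:
        raise FormulaError("empty formula")
    charge = Fraction(0)
    m = _CHARGE_RE.search(t)
    body = t
    if m:
        sign = m.group("s1") or m.group("s2") or m.group("s3")
        digits = m.group("n1") or m.group("n2") or "1"
        charge = Fraction(digits) * (1 if sign == "+" else -1)
        body = t[: m.start()]
    if not body:
        raise FormulaError(f"formula {text!r} has a charge but no atoms")
    if "^" in body:
        raise FormulaError(f"malformed charge suffix in {text!r}")
    counts: dict[str, Fraction] = {}
    pos = 0
    while pos < len(body):
        tok = _ELEMENT_TOKEN_RE.match(body, pos)
        if tok is None or not tok.group(0):
            raise FormulaError(f"cannot parse formula {text!r} at {body[pos:]!r}")
        sym = tok.group(1)
        if sym not in _ELEMENT_SYMBOLS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, Fraction(0)) + Fraction(tok.group(2) or 1)
        pos = tok.end()
    return ElementalComposition(counts, charge)


def _fmt_rational(x: Fraction) -> str:
    return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def compose_formula(comp: ElementalComposition) -> str:
    """Canonical ASCII formula: Hill order, caret charge dialect (``SO3^2-``)."""
    syms = sorted(comp.counts)
    if "C" in comp.counts:
        ordered = ["C"] + (["H"] if "H" in comp.counts else [])
        ordered += [s for s in syms if s not in ("C", "H")]
    else:
        ordered = syms
    parts = []
    for sym in ordered:
        n = comp.counts[sym]
        parts.append(sym if n == 1 else f"{sym}{_fmt_rational(n)}")
    body = "".join(parts)
    q = comp.charge
    if q == 0:
        suffix = ""
    elif abs(q) == 1:
        suffix = "+" if q > 0 else "-"
    else:
        suffix = f"^{_fmt_rational(abs(q))}{'+' if q > 0 else '-'}"
    return body + suffix


@dataclass
class Compound:
    """A chemical species with composition, phase and formation energy.

    ``dgf_standard`` is the standard Gibbs energy of formation in kJ/mol at
    25 degC (H+ at activity 1); ``None`` means unknown / to be calibrated.
    """

    id: str
    composition: ElementalComposition
    phase: str = "aqueous"
    dgf_standard: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not self.composition.counts:
            raise ValueError(f"compound {self.id!r} has no atoms")

    @property
    def is_proton(self) -> bool:
        return self.composition.counts == {"H": Fraction(1)} and self.composition.charge == 1


class CompoundTable:
    """Ordered registry of :class:`Compound`, keyed by id.

    ``resolve`` also accepts a raw formula string and matches it against the
    registered compositions, so reactions written with formulas and reactions
    written with ids land on the same keys.
    """

    def __init__(self, compounds: Iterable[Compound] = ()) -> None:
        self._by_id: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.id in self._by_id:
            raise ValueError(f"duplicate compound id {compound.id!r}")
        self._by_id[compound.id] = compound

    def __getitem__(self, cid: str) -> Compound:
        try:
            return self._by_id[cid]
        except KeyError:
            raise UnknownCompoundError(f"no compound with id {cid!r}") from None

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._by_id)

    def set_dgf(self, cid: str, value: float, source: str = "calibrated") -> None:
        c = self[cid]
        c.dgf_standard = float(value)
        if source:
            c.source = source

    def resolve(self, token: str) -> Compound:
        """Look a species up by id, exact formula string, or composition."""
        if token in self._by_id:
            return self._by_id[token]
        try:
            comp = parse_formula(token)
        except FormulaError:
            raise UnknownCompoundError(
                f"species {token!r} is neither a known id nor a formula"
            ) from None
        matches = [c for c in self if c.composition == comp]
        if not matches:
            raise UnknownCompoundError(f"no compound matching formula {token!r}")
        if len(matches) > 1:
            ids = [c.id for c in matches]
            raise UnknownCompoundError(f"formula {token!r} is ambiguous: {ids}")
        return matches[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompoundTable":
        """Read the TSV interchange format (id, formula, charge, phase,
        dGf_kJ_per_mol, source; '#' comments)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"id", "formula", "charge", "phase", "dGf_kJ_per_mol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"compound table missing columns: {sorted(missing)}")
        table = cls()
        for row in df.itertuples(index=False):
            comp = parse_formula(row.formula)
            declared = Fraction(str(row.charge))
            if declared != comp.charge:
                raise ValueError(
                    f"compound {row.id!r}: declared charge {declared} does not "
                    f"match formula {row.formula!r} ({comp.charge})"
                )
            raw = row.dGf_kJ_per_mol
            dgf = None if (pd.isna(raw) or str(raw).strip() == "") else float(raw)
            source = "" if pd.isna(getattr(row, "source", "")) else str(getattr(row, "source", ""))
            table.add(Compound(str(row.id), comp, str(row.phase), dgf, source))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for c in self:
            rows.append(
                {
                    "id": c.id,
                    "formula": compose_formula(c.composition),
                    "charge": _fmt_rational(c.composition.charge),
                    "phase": c.phase,
                    "dGf_kJ_per_mol": "" if c.dgf_standard is None else repr(c.dgf_standard),
                    "source": c.source,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def degree_of_reduction(species: "Compound | ElementalComposition") -> Fraction:
    """Electron equivalents per mole relative to CO2/H2O/H+/SO4^2-/NH4+/Br-.

    Examples: H2 -> 2, acetate -> 8, oleate -> 102, sulfite -> 2, and exactly
    0 for every reference species.  Raises ``ValueError`` for an element with
    no declared reference state.
    """
    comp = species.composition if isinstance(species, Compound) else species
    gamma = -comp.charge
    for el, n in comp.counts.items():
        try:
            gamma += _GAMMA_WEIGHTS[el] * n
        except KeyError:
            raise ValueError(
                f"no electron-equivalent reference state declared for element {el!r}"
            ) from None
    return gamma


def calibrate_formation_energy(reaction, table: CompoundTable, target_dg_prime: float, cond=None) -> float:
    """Back-derive the formation energy of the single unknown compound.

    Solves ``delta_g_standard_prime(reaction) == target_dg_prime`` for the one
    compound in ``reaction`` whose ``dgf_standard`` is ``None`` (the proton is
    by convention never an unknown).  The returned value, inserted into the
    table, reproduces the target to machine precision.
    """
    from .reactions import ThermoConditions  # local import avoids a cycle

    cond = cond if cond is not None else ThermoConditions()
    known = 0.0
    nu_h = Fraction(0)
    unknowns: list[tuple[Compound, Fraction]] = []
    for cid, nu in reaction.stoich.items():
        c = table.resolve(cid)
        if c.is_proton:
            nu_h += nu
            continue
        if c.dgf_standard is None:
            unknowns.append((c, nu))
        else:
            known += float(nu) * c.dgf_standard
    if len(unknowns) != 1:
        ids = [c.id for c, _ in unknowns]
        raise CalibrationError(
            f"need exactly one unknown formation energy, found {len(unknowns)} {ids}"
        )
    compound, nu = unknowns[0]
    return (float(target_dg_prime) - known - float(nu_h) * cond.proton_term_kj) / float(nu)
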