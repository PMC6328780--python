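"""Reactions: parsing, balance checks, transformed Gibbs energies, exact algebra.

Sign convention: reactants carry negative stoichiometric coefficients,
products positive, so combining reactions is plain linear algebra over the
species vector space.  Stoichiometry is exact (:class:`fractions.Fraction`);
only energies are floats.

The standard transformed Gibbs energy at pH p is::

    dG0' = sum_nu(i != H+) nu_i * dGf0_i  +  nu_H+ * R*T*ln(10^-p)

i.e. the proton contributes no formation energy (biochemical convention) and
enters only through the pH term.  At non-standard activities::

    dG = dG0' + R*T * sum_i nu_i * ln(a_i)

with gases counted as partial pressure over 1e5 Pa and solutes as molar
activity; unspecified activities default to 1.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

from .chem import (
    CompoundTable,
    FormulaError,
    UnknownCompoundError,
    compose_formula,
    degree_of_reduction,
    parse_formula,
)

__all__ = [
    "Reaction",
    "ThermoConditions",
    "BalanceReport",
    "ReactionParseError",
    "MissingFormationEnergyError",
    "UnderdeterminedError",
    "Infeasible",
    "parse_reaction",
    "check_balance",
    "delta_g_standard_prime",
    "delta_g_actual",
    "combine",
    "decompose",
]

Rational = Union[int, Fraction]


class ReactionParseError(ValueError):
    """A reaction equation string could not be parsed."""


class MissingFormationEnergyError(ValueError):
    """A compound needed for an energy computation has no formation energy."""


class UnderdeterminedError(ValueError):
    """The decomposition has multiple exact solutions."""

    def __init__(self, message: str, rank: int, n_basis: int) -> None:
        super().__init__(message)
        self.rank = rank
        self.n_basis = n_basis


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature, pH and gas constant defining the transformed standard state."""

    temperature: float = 298.15  # K
    ph: float = 7.0
    gas_constant: float = 8.314  # J mol^-1 K^-1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError("pH must lie in [0, 14]")

    @property
    def rt_kj(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature / 1000.0

    @property
    def proton_term_kj(self) -> float:
        """R*T*ln(10^-pH): the per-proton transformed-state correction, kJ/mol."""
        return self.rt_kj * math.log(10.0) * (-self.ph)


def _coerce(x: Rational | float | str) -> Fraction:
    # Fraction(str(float)) keeps decimal coefficients like 7.5 exact.
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


@dataclass(eq=False)
class Reaction:
    """Signed stoichiometric map over species keys (ids or canonical formulas)."""

    stoich: dict[str, Fraction]
    label: str | None = None

    def __post_init__(self) -> None:
        self.stoich = {sp: _coerce(nu) for sp, nu in self.stoich.items() if nu != 0}

    def __eq__(self, other: object) -> bool:
        # label is metadata; identity is the stoichiometry
        if not isinstance(other, Reaction):
            return NotImplemented
        return self.stoich == other.stoich

    def coefficient(self, species: str) -> Fraction:
        return self.stoich.get(species, Fraction(0))

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {sp: -nu for sp, nu in self.stoich.items() if nu < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {sp: nu for sp, nu in self.stoich.items() if nu > 0}

    @property
    def is_empty(self) -> bool:
        return not self.stoich

    def scaled(self, c: Rational) -> "Reaction":
        c = _coerce(c)
        return Reaction({sp: c * nu for sp, nu in self.stoich.items()}, label=self.label)

    def equation(self) -> str:
        """Render as ``"A + 2 B -> 3 C"`` with decimal coefficients where exact."""
        def side(items: Mapping[str, Fraction]) -> str:
            terms = []
            for sp, nu in items.items():
                terms.append(sp if nu == 1 else f"{_fmt_coeff(nu)} {sp}")
            return " + ".join(terms) if terms else "(nothing)"

        return f"{side(self.reactants)} -> {side(self.products)}"

    def __repr__(self) -> str:
        tag = f"{self.label}: " if self.label else ""
        return f"<Reaction {tag}{self.equation()}>"


def _fmt_coeff(f: Fraction) -> str:
    if f.denominator == 1:
        return str(f.numerator)
    x = float(f)
    if Fraction(str(x)) == f:  # terminating decimal, e.g. 7.5, 3.75
        return f"{x:g}"
    return f"{f.numerator}/{f.denominator}"


_ARROWS = ("-->", "->", "→", "⟶", "=>", "⇒")


def _split_terms(side: str) -> list[str]:
    side = side.strip()
    if side.startswith("+"):  # tolerate a stray leading plus
        side = side[1:].lstrip()
    # A separating '+' has whitespace before it; a charge '+' never does.
    terms = [t.strip() for t in re.split(r"\s\+\s*", side)]
    return [t for t in terms if t]


_COEFF_RE = re.compile(r"(\d+(?:\.\d+)?|\d+/\d+)\s*")


def _parse_term(term: str) -> tuple[Fraction, str]:
    m = _COEFF_RE.match(term)
    if m and term[m.end():]:
        return _coerce(m.group(1)), term[m.end():]
    return Fraction(1), term


def _canonical_species(token: str, table: CompoundTable | None) -> str:
    if table is not None:
        return table.resolve(token).id
    try:
        return compose_formula(parse_formula(token))
    except FormulaError:
        return token  # a plain compound id


def parse_reaction(text: str, table: CompoundTable | None = None, label: str | None = None) -> Reaction:
    """Parse ``"A + 2 B -> 3 C + D"`` with formulas or compound ids.

    Tolerates unicode arrows, unicode minus signs, subscript underscores and
    the missing-space dialect ``"+4H_2_ +H^+^"``.  With a ``table``, species
    are canonicalised to compound ids; duplicated species are summed and
    species cancelling to zero are dropped (with a warning if the whole
    reaction cancels).
    """
    t = text
    for arrow in _ARROWS:
        t = t.replace(arrow, "->" if arrow != "->" else arrow)
    if "->" not in t:
        raise ReactionParseError(f"no arrow separator in {text!r}")
    lhs, rhs = t.split("->", 1)
    stoich: dict[str, Fraction] = {}
    for side, sign in ((lhs, -1), (rhs, +1)):
        for term in _split_terms(side):
            coeff, token = _parse_term(term)
            try:
                key = _canonical_species(token, table)
            except UnknownCompoundError as err:
                raise ReactionParseError(f"unparseable term {term!r}: {err}") from None
            stoich[key] = stoich.get(key, Fraction(0)) + sign * coeff
    stoich = {sp: nu for sp, nu in stoich.items() if nu != 0}
    if not stoich:
        warnings.warn(f"reaction {text!r} cancels to nothing", stacklevel=2)
    return Reaction(stoich, label=label)


@dataclass(frozen=True)
class BalanceReport:
    """Exact conservation residuals (products minus reactants)."""

    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction
    electron_residual: Fraction

    @property
    def is_balanced(self) -> bool:
        return (
            all(v == 0 for v in self.element_residuals.values())
            and self.charge_residual == 0
            and self.electron_residual == 0
        )


def _resolve_composition(token: str, table: CompoundTable | None):
    if table is not None:
        return table.resolve(token).composition
    return parse_formula(token)


def check_balance(reaction: Reaction, table: CompoundTable | None = None) -> BalanceReport:
    """Exact rational residuals for every element, charge and electron equivalents."""
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    gamma = Fraction(0)
    for sp, nu in reaction.stoich.items():
        comp = _resolve_composition(sp, table)
        for el, n in comp.counts.items():
            elements[el] = elements.get(el, Fraction(0)) + nu * n
        charge += nu * comp.charge
        gamma += nu * degree_of_reduction(comp)
    return BalanceReport(elements, charge, gamma)


def delta_g_standard_prime(reaction: Reaction, table: CompoundTable, cond: ThermoConditions | None = None) -> float:
    """Standard transformed Gibbs energy dG0' in kJ per formula reaction."""
    cond = cond if cond is not None else ThermoConditions()
    total = 0.0
    nu_h = Fraction(0)
    for sp, nu in reaction.stoich.items():
        c = table.resolve(sp)
        if c.is_proton:
            nu_h += nu
            continue
        if c.dgf_standard is None:
            raise MissingFormationEnergyError(
                f"compound {c.id!r} has no standard formation energy"
            )
        total += float(nu) * c.dgf_standard
    return total + float(nu_h) * cond.proton_term_kj


def delta_g_actual(
    reaction: Reaction,
    table: CompoundTable,
    cond: ThermoConditions | None = None,
    activities: Mapping[str, float] | None = None,
) -> float:
    """dG = dG0' + R*T * sum nu*ln(a) at the given activities / partial pressures.

    The proton is controlled through ``cond.ph``, never through ``activities``;
    any species not listed is at activity 1.
    """
    cond = cond if cond is not None else ThermoConditions()
    dg = delta_g_standard_prime(reaction, table, cond)
    for sp, a in (activities or {}).items():
        if a <= 0:
            raise ValueError(f"activity of {sp!r} must be positive, got {a}")
        c = table.resolve(sp)
        if c.is_proton:
            raise ValueError("set the proton level through ThermoConditions.ph")
        dg += float(reaction.coefficient(c.id)) * cond.rt_kj * math.log(a)
    return dg


def combine(terms: Iterable[tuple[Reaction, Rational | float]], label: str | None = None) -> Reaction:
    """Species-wise signed sum ``sum_i c_i * r_i``; zero coefficients are dropped.

    dG0' is linear under this operation: the energy of the result equals the
    same linear combination of the component energies.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("combine() needs at least one (reaction, coefficient) pair")
    stoich: dict[str, Fraction] = {}
    for rxn, c in terms:
        c = _coerce(c)
        for sp, nu in rxn.stoich.items():
            stoich[sp] = stoich.get(sp, Fraction(0)) + c * nu
    return Reaction(stoich, label=label)


@dataclass(frozen=True)
class Infeasible:
    """The target is not in the span of the basis; carries the least-squares residual."""

    residual: Mapping[str, Fraction]

    def __bool__(self) -> bool:
        return False


def decompose(target: Reaction, basis: Sequence[Reaction]) -> tuple[Fraction, ...] | Infeasible:
    """Exact coefficients c with ``combine(zip(basis, c)) == target``.

    Solved as a rational linear system over the union of species.  Raises
    :class:`UnderdeterminedError` when multiple exact solutions exist
    (reporting the rank); returns :class:`Infeasible` with the exact
    least-squares residual when no solution exists.
    """
    import sympy

    basis = list(basis)
    if not basis:
        raise ValueError("decompose() needs a nonempty basis")
    species = sorted(set(target.stoich).union(*(set(b.stoich) for b in basis)))
    A = sympy.Matrix(
        [[sympy.Rational(b.stoich.get(sp, Fraction(0))) for b in basis] for sp in species]
    )
    b = sympy.Matrix([sympy.Rational(target.stoich.get(sp, Fraction(0))) for sp in species])
    rank_a = A.rank()
    aug = A.row_join(b)
    if aug.rank() > rank_a:
        x = A.pinv() * b  # exact least squares
        res = A * x - b
        residual = {
            sp: Fraction(int(v.p), int(v.q)) for sp, v in zip(species, res) if v != 0
        }
        return Infeasible(residual)
    if rank_a < len(basis):
        raise UnderdeterminedError(
            f"decomposition underdetermined: basis rank {rank_a} < {len(basis)} reactions",
            rank=rank_a,
            n_basis=len(basis),
        )
    x = A.pinv() * b  # unique since full column rank and consistent
    return tuple(Fraction(int(v.p), int(v.q)) for v in x)
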