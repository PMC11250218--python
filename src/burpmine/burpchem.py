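"""Elemental-formula arithmetic and burpitide modification chemistry.

Burpitides are RiPPs whose mature products are macrocyclic peptides built
from a short (typically 4-8 residue) core.  Families differ in which
side-chain crosslinks and tailoring steps they apply: cyclopeptide
alkaloids carry a Tyr-phenol-O to carbon ether macrocycle, Rhamnaceae
members additionally lose the C-terminal carboxyl (oxidative
decarboxylation with enamide formation) and are N-methylated, while
stephanotic-acid-type molecules (moroidin) use a Trp-indole-C to carbon
crosslink.  This module models all of that at the elemental-formula level:
a compound prediction is a core peptide plus a multiset of formula deltas.

Monoisotopic element masses are fixed constants (CODATA/NIST values,
carbon-12 scale) so every downstream m/z is reproducible to the micro-Da.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

__all__ = [
    "Formula",
    "ModificationSpec",
    "CompoundPrediction",
    "MODIFICATIONS",
    "FAMILY_RULESETS",
    "PROTON_MASS",
    "peptide_formula",
    "apply_modifications",
    "enumerate_candidates",
    "fragment_ions",
]

#: Exact monoisotopic masses, Da.
ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
}

PROTON_MASS = 1.0072765
ELECTRON_MASS = 0.00054858
NA_MASS = 22.98976928
K_MASS = 38.96370649

_HILL_ORDER = ("C", "H", "N", "O", "S")


class Formula(Counter):
    """Element -> count map over {C,H,N,O,S}; supports signed deltas.

    Addition/subtraction are elementwise; ``mass`` is the exact
    monoisotopic mass.  Negative counts are legal for modification deltas
    but not for a realised compound formula.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        bad = set(self) - set(ELEMENT_MASS)
        if bad:
            raise ValueError(f"unsupported elements: {sorted(bad)}")

    def __add__(self, other: "Formula") -> "Formula":
        out = Formula()
        for el in set(self) | set(other):
            out[el] = self.get(el, 0) + other.get(el, 0)
        return out

    def __sub__(self, other: "Formula") -> "Formula":
        out = Formula()
        for el in set(self) | set(other):
            out[el] = self.get(el, 0) - other.get(el, 0)
        return out

    def __neg__(self) -> "Formula":
        return Formula({el: -n for el, n in self.items()})

    @property
    def mass(self) -> float:
        return sum(ELEMENT_MASS[el] * n for el, n in self.items())

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            n = self.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts) or "0"

    def is_realizable(self) -> bool:
        return all(n >= 0 for n in self.values())


def _f(**counts: int) -> Formula:
    return Formula(counts)


WATER = _f(H=2, O=1)

#: Residue (amino acid minus water) formulas for the 20 standard residues.
RESIDUE_FORMULAS = {
    "G": _f(C=2, H=3, N=1, O=1),
    "A": _f(C=3, H=5, N=1, O=1),
    "S": _f(C=3, H=5, N=1, O=2),
    "P": _f(C=5, H=7, N=1, O=1),
    "V": _f(C=5, H=9, N=1, O=1),
    "T": _f(C=4, H=7, N=1, O=2),
    "C": _f(C=3, H=5, N=1, O=1, S=1),
    "L": _f(C=6, H=11, N=1, O=1),
    "I": _f(C=6, H=11, N=1, O=1),
    "N": _f(C=4, H=6, N=2, O=2),
    "D": _f(C=4, H=5, N=1, O=3),
    "Q": _f(C=5, H=8, N=2, O=2),
    "K": _f(C=6, H=12, N=2, O=1),
    "E": _f(C=5, H=7, N=1, O=3),
    "M": _f(C=5, H=9, N=1, O=1, S=1),
    "H": _f(C=6, H=7, N=3, O=1),
    "F": _f(C=9, H=9, N=1, O=1),
    "R": _f(C=6, H=12, N=4, O=1),
    "Y": _f(C=9, H=9, N=1, O=2),
    "W": _f(C=11, H=10, N=2, O=1),
}

RESIDUE_MASSES = {aa: f.mass for aa, f in RESIDUE_FORMULAS.items()}


def peptide_formula(seq: str) -> Formula:
    """Elemental formula of a linear peptide: sum of residues plus water."""
    if not seq:
        raise ValueError("empty peptide sequence")
    out = Formula(WATER)
    for aa in seq:
        try:
            out = out + RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(f"nonstandard residue {aa!r} in {seq!r}") from None
    return out


def peptide_mass(seq: str) -> float:
    return peptide_formula(seq).mass


# ---------------------------------------------------------------------------
# Modification registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModificationSpec:
    """A named formula delta with a site constraint.

    ``constraint(core, prior_mods)`` decides whether the modification may
    be applied to ``core`` given the modifications already applied; it is
    checked for every application, so a second crosslink of the same kind
    needs a second eligible site.
    """

    name: str
    delta: Formula
    site: str
    constraint: Callable[[str, Sequence[str]], bool]

    def allowed(self, core: str, prior: Sequence[str]) -> bool:
        return self.constraint(core, prior)


def _requires_terminal_tyr(core: str, prior: Sequence[str]) -> bool:
    return core.endswith("Y")


def _requires_tyr_site(core: str, prior: Sequence[str]) -> bool:
    # One ether per available Tyr; the first one must engage the
    # C-terminal Tyr phenol (the subclass-defining macrocycle).
    n_prior = sum(1 for m in prior if m == "ether_crosslink")
    if n_prior == 0:
        return core.endswith("Y")
    return n_prior < core.count("Y")


def _requires_trp(core: str, prior: Sequence[str]) -> bool:
    return sum(1 for m in prior if m == "cc_crosslink") < core.count("W")


def _always(core: str, prior: Sequence[str]) -> bool:
    return True


MODIFICATIONS: dict[str, ModificationSpec] = {
    # Tyr-phenol-O to carbon oxidative coupling closing the macrocycle.
    "ether_crosslink": ModificationSpec(
        "ether_crosslink", -_f(H=2), "requires Tyr (first: C-terminal Tyr)",
        _requires_tyr_site),
    # Trp-indole-C to carbon crosslink (stephanotic acid / moroidin type).
    "cc_crosslink": ModificationSpec(
        "cc_crosslink", -_f(H=2), "requires Trp", _requires_trp),
    # Backbone N-methylation; may be applied repeatedly.
    "n_methyl": ModificationSpec(
        "n_methyl", _f(C=1, H=2), "N-terminal amine or backbone amide",
        _always),
    # Loss of the C-terminal carboxyl with enamide formation.
    "oxidative_decarboxylation": ModificationSpec(
        "oxidative_decarboxylation", -_f(C=1, O=2, H=2),
        "requires C-terminal Tyr", _requires_terminal_tyr),
    # Provisional N-terminal transamination-style alpha-keto delta.
    "alpha_keto": ModificationSpec(
        "alpha_keto", _f(O=1) - _f(N=1, H=3), "N-terminal amine", _always),
}


@dataclass
class CompoundPrediction:
    """A core peptide with applied modifications and its mass arithmetic."""

    core: str
    modifications: tuple[str, ...]
    formula: Formula
    neutral_mass: float
    adduct_mz: dict[str, float]
    ruleset: str | None = None

    def __post_init__(self):
        if not self.formula.is_realizable():
            raise ValueError(
                f"formula {self.formula.hill()} has negative element counts")


def _adducts(neutral: float) -> dict[str, float]:
    return {
        "M+H": neutral + PROTON_MASS,
        "M+Na": neutral + NA_MASS - ELECTRON_MASS,
        "M+K": neutral + K_MASS - ELECTRON_MASS,
        "M+2H": (neutral + 2 * PROTON_MASS) / 2.0,
    }


class ConstraintError(ValueError):
    """A modification's site constraint is not satisfied by the core."""


def apply_modifications(core: str, mods: Iterable[str],
                        ruleset: str | None = None) -> CompoundPrediction:
    """Apply named modifications to a core peptide.

    Order of application does not affect the result (formula deltas
    commute) but site constraints are checked cumulatively, so e.g. two
    ether crosslinks need two tyrosines.
    """
    mods = tuple(mods)
    formula = peptide_formula(core)
    applied: list[str] = []
    # Constraint checking is order-insensitive: apply in sorted order.
    for name in sorted(mods):
        try:
            spec = MODIFICATIONS[name]
        except KeyError:
            raise KeyError(
                f"unknown modification {name!r}; known: "
                f"{sorted(MODIFICATIONS)}") from None
        if not spec.allowed(core, applied):
            raise ConstraintError(
                f"modification {name!r} not allowed on core {core!r} "
                f"({spec.site})")
        formula = formula + spec.delta
        applied.append(name)
    neutral = formula.mass
    return CompoundPrediction(core=core, modifications=mods, formula=formula,
                              neutral_mass=neutral,
                              adduct_mz=_adducts(neutral), ruleset=ruleset)


# ---------------------------------------------------------------------------
# Family rulesets
# ---------------------------------------------------------------------------

#: mandatory modifications + optional blocks (each block: mod name, max count)
FAMILY_RULESETS: dict[str, dict] = {
    # Tyr ether macrocycle, oxidative decarboxylation, 0-2 N-methyls
    "rhamnaceae": {
        "mandatory": ("ether_crosslink", "oxidative_decarboxylation"),
        "optional": (("n_methyl", 2),),
    },
    # Tyr ether macrocycle only (Tyr carboxyl intact), 0-2 N-methyls
    "rubiaceae": {
        "mandatory": ("ether_crosslink",),
        "optional": (("n_methyl", 2),),
    },
    # Trp-indole C-C crosslink, optionally bicyclic (second crosslink)
    "stephanotic": {
        "mandatory": ("cc_crosslink",),
        "optional": (("cc_crosslink", 1),),
    },
    # Two Tyr-derived ether linkages, optional alpha-keto N terminus
    "amaranthaceae_bicyclic": {
        "mandatory": ("ether_crosslink", "ether_crosslink"),
        "optional": (("alpha_keto", 1),),
    },
}


def enumerate_candidates(core: str, family_ruleset: str) -> list[CompoundPrediction]:
    """All modification combinations a family ruleset allows on a core.

    Returns predictions deduplicated by elemental formula; a core that
    cannot satisfy the mandatory site constraints yields an empty list.
    """
    try:
        rules = FAMILY_RULESETS[family_ruleset]
    except KeyError:
        raise KeyError(
            f"unknown ruleset {family_ruleset!r}; known: "
            f"{sorted(FAMILY_RULESETS)}") from None
    optional = rules["optional"]
    counts = [range(nmax + 1) for _, nmax in optional]
    out: list[CompoundPrediction] = []
    seen: set[str] = set()
    for combo in itertools.product(*counts):
        mods = list(rules["mandatory"])
        for (name, _), n in zip(optional, combo):
            mods.extend([name] * n)
        try:
            pred = apply_modifications(core, mods, ruleset=family_ruleset)
        except ConstraintError:
            continue
        key = pred.formula.hill()
        if key not in seen:
            seen.add(key)
            out.append(pred)
    return out


# ---------------------------------------------------------------------------
# Fragment ions
# ---------------------------------------------------------------------------

CO_MASS = ELEMENT_MASS["C"] + ELEMENT_MASS["O"]
#: immonium ion = residue mass - CO + H  (i.e. residue - 26.98709)
IMINIUM_DELTA = -(CO_MASS) + ELEMENT_MASS["H"]

_CROSSLINKS = {"ether_crosslink", "cc_crosslink"}


def _linear_by(seq: str) -> list[tuple[str, float]]:
    out = []
    acc = 0.0
    for i, aa in enumerate(seq[:-1], start=1):
        acc += RESIDUE_MASSES[aa]
        out.append((f"b{i}", acc + PROTON_MASS))
    # y ions, built from the C terminus
    acc = WATER.mass
    ys = []
    for i, aa in enumerate(reversed(seq[1:]), start=1):
        acc += RESIDUE_MASSES[aa]
        ys.append((f"y{i}", acc + PROTON_MASS))
    return out + ys


def fragment_ions(prediction: CompoundPrediction,
                  series: Sequence[str] = ("b", "y", "iminium"),
                  tol: float = 1e-4) -> list[tuple[str, float]]:
    """Predicted MS/MS fragment m/z values (singly charged).

    Macrocyclic predictions (any crosslink applied) are ring-opened at
    every backbone amide, giving one linearization per residue; b/y ions
    are generated from each linearization on the unmodified core backbone.
    Immonium (iminium) ions are residue-diagnostic: residue mass - CO + H.
    Near-duplicate m/z values (within ``tol`` Da) are merged.
    """
    core = prediction.core
    cyclic = any(m in _CROSSLINKS for m in prediction.modifications)
    linearizations = ([core[i:] + core[:i] for i in range(len(core))]
                      if cyclic else [core])
    raw: list[tuple[str, float]] = []
    for j, lin in enumerate(linearizations):
        prefix = f"o{j}." if len(linearizations) > 1 else ""
        for label, mz in _linear_by(lin):
            kind = label[0]
            if kind in series:
                raw.append((prefix + label, mz))
    if "iminium" in series:
        for aa in sorted(set(core)):
            raw.append((f"imm{aa}", RESIDUE_MASSES[aa] + IMINIUM_DELTA))
    raw.sort(key=lambda t: (t[1], t[0]))
    merged: list[tuple[str, float]] = []
    for label, mz in raw:
        if merged and abs(mz - merged[-1][1]) <= tol:
            continue
        merged.append((label, mz))
    return merged
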