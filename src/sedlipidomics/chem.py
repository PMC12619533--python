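"""Elemental formulas, adduct arithmetic, and the stylized lipid chemistry model.

Lipid species are built from a small set of structural blocks (sphingoid
base, fatty acid, glycerol backbones, headgroups). The same block model is
used by the synthetic spectrum generator and by the default annotation
rulebook, so diagnostic fragments and theoretical precursor masses are
consistent by construction.

Formulas are plain ``{element: count}`` dicts over C, H, N, O, P, S and Na.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from pyteomics import mass as _pmass

ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O", "P", "S", "Na"})

#: Proton mass used for fragment m/z arithmetic (Da).
PROTON = 1.007276

#: Adduct mass deltas (Da) relative to the neutral monoisotopic mass,
#: positive-ion mode, singly charged.
ADDUCT_DELTAS: dict[str, float] = {
    "[M+H]+": 1.007276,
    "[M+NH4]+": 18.033823,
    "[M+Na]+": 22.989218,
    "[M+H-H2O]+": -17.003289,
}

H2O = 18.0105646863
CH2 = 14.0156500642
H2 = 2.0156500642
O_MASS = 15.9949146196
HEXOSE = 162.0528234315  # C6H10O5, glycosidic residue

#: Neutral losses recognised when chaining homolog series.
SERIES_GAPS: dict[str, float] = {
    "CH2": CH2,
    "H2": H2,
    "O": O_MASS,
    "hexose": HEXOSE,
}

# Subclass-diagnostic neutral losses (Da).
LOSS_SULFATE_SO3 = 79.95682
LOSS_SULFATE_H2SO4 = 97.96738
LOSS_SULFONO = 81.97246  # H2SO3
FRAG_LYSINE = 129.10224  # protonated lysine residue
FRAG_PHOSPHOCHOLINE = 184.0733

SPHINGO_SUBCLASSES = (
    "Cer",
    "1-deoxyCer",
    "1-O-acylCer",
    "Gly-Cer",
    "Lysine-Cer",
    "Sulfono-Cer",
    "Sulfate-Cer",
)

LIPID_CLASSES = (
    "sterol",
    "sterol-ester",
    "TAG",
    "pigment",
    "PC",
    "PE",
    "PG",
    "PI",
    "betaine",
    "1G-DEG",
    "isoGDGT",
    "alkenone",
    "sphingolipid",
    "other",
)


class FormulaError(ValueError):
    """Raised for formulas containing unsupported elements."""


def _as_counter(formula: Mapping[str, int] | str) -> Counter:
    if isinstance(formula, str):
        comp = _pmass.Composition(formula=formula) if formula else Counter()
        formula = dict(comp)
    c = Counter({k: int(v) for k, v in formula.items() if v})
    bad = set(c) - ALLOWED_ELEMENTS
    if bad:
        raise FormulaError(f"unsupported element(s) {sorted(bad)} in formula")
    if any(v < 0 for v in c.values()):
        raise FormulaError(f"negative element count in {dict(c)}")
    return c


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of an elemental formula over C,H,N,O,P,S,Na."""
    c = _as_counter(formula)
    if not c:
        return 0.0
    return float(_pmass.calculate_mass(composition=_pmass.Composition(c)))


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    c = _as_counter(formula)
    order = ["C", "H"] + sorted(k for k in c if k not in ("C", "H"))
    out = []
    for el in order:
        n = c.get(el, 0)
        if n == 1:
            out.append(el)
        elif n > 1:
            out.append(f"{el}{n}")
    return "".join(out)


def adduct_mz(mono_mass: float, adduct: str) -> float:
    """m/z of a singly charged positive adduct of a neutral of given mass."""
    try:
        return mono_mass + ADDUCT_DELTAS[adduct]
    except KeyError:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_DELTAS)}") from None


def combine(*parts: Mapping[str, int], minus_h2o: int = 0) -> Counter:
    """Sum formulas, removing ``minus_h2o`` waters (condensation bonds)."""
    total: Counter = Counter()
    for p in parts:
        total.update(_as_counter(p))
    total["H"] -= 2 * minus_h2o
    total["O"] -= minus_h2o
    if any(v < 0 for v in total.values()):
        raise FormulaError("condensation removed more atoms than available")
    return +total


# ---------------------------------------------------------------------------
# structural blocks


def fatty_acid(carbons: int, unsat: int = 0) -> Counter:
    """Free fatty acid CnH(2n-2u)O2."""
    if carbons < 2 or unsat < 0 or 2 * carbons - 2 * unsat < 4:
        raise FormulaError(f"infeasible fatty acid C{carbons}:{unsat}")
    return Counter({"C": carbons, "H": 2 * carbons - 2 * unsat, "O": 2})


def sphingoid_base(carbons: int, unsat: int = 0, oxygens: int = 2) -> Counter:
    """Long-chain amino alcohol backbone CnH(2n+3-2u)N O_ox.

    ``oxygens=2`` is the common dihydroxy (d-type) base; ``oxygens=1`` is the
    1-deoxy base.
    """
    if carbons < 6 or unsat < 0 or oxygens < 1:
        raise FormulaError(f"infeasible sphingoid base {carbons}:{unsat};O{oxygens}")
    return Counter({"C": carbons, "H": 2 * carbons + 3 - 2 * unsat, "N": 1, "O": oxygens})


GLYCEROL = Counter({"C": 3, "H": 8, "O": 3})
GPC_BACKBONE = Counter({"C": 8, "H": 20, "N": 1, "O": 6, "P": 1})
GPE_BACKBONE = Counter({"C": 5, "H": 14, "N": 1, "O": 6, "P": 1})
GPG_BACKBONE = Counter({"C": 6, "H": 15, "O": 8, "P": 1})
GPI_BACKBONE = Counter({"C": 9, "H": 19, "O": 11, "P": 1})
BETAINE_BACKBONE = Counter({"C": 10, "H": 21, "N": 1, "O": 5})  # DGTS-like
HEXOSE_RESIDUE = Counter({"C": 6, "H": 10, "O": 5})
LYSINE_RESIDUE = Counter({"C": 6, "H": 12, "N": 2, "O": 1})
SULFONATE = Counter({"S": 1, "O": 3})  # -SO3H replacing H
SULFATE = Counter({"S": 1, "O": 4})  # -OSO3H replacing H
PHEOPHYTIN_A = Counter({"C": 55, "H": 74, "N": 4, "O": 5})


@dataclass(frozen=True)
class LipidSpecies:
    """A chemically defined lipid: class, chains, formula, mass, shorthand."""

    lipid_class: str
    subclass: str | None = None
    base_carbons: int = 0
    base_unsat: int = 0
    fa_carbons: int = 0
    fa_unsat: int = 0
    extra_fa_carbons: int = 0
    hydroxyl_count: int = 2
    formula: Mapping[str, int] = field(default_factory=dict)
    mono_mass: float = 0.0
    shorthand: str = ""

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.lipid_class == "sphingolipid" and self.subclass not in SPHINGO_SUBCLASSES:
            raise ValueError(f"unknown sphingolipid subclass {self.subclass!r}")


def sphingolipid_formula(
    subclass: str,
    base_carbons: int,
    base_unsat: int,
    fa_carbons: int,
    fa_unsat: int,
    extra_fa_carbons: int = 0,
) -> Counter:
    """Formula of a sphingolipid from its subclass and chain descriptor."""
    oxygens = 1 if subclass == "1-deoxyCer" else 2
    cer = combine(
        sphingoid_base(base_carbons, base_unsat, oxygens),
        fatty_acid(fa_carbons, fa_unsat),
        minus_h2o=1,
    )
    if subclass in ("Cer", "1-deoxyCer"):
        return cer
    if subclass == "1-O-acylCer":
        if not extra_fa_carbons:
            raise FormulaError("1-O-acylCer requires extra_fa_carbons")
        return combine(cer, fatty_acid(extra_fa_carbons, 0), minus_h2o=1)
    if subclass == "Gly-Cer":
        return combine(cer, HEXOSE_RESIDUE)
    if subclass == "Lysine-Cer":
        return combine(cer, LYSINE_RESIDUE)
    if subclass == "Sulfono-Cer":
        return combine(cer, SULFONATE)
    if subclass == "Sulfate-Cer":
        return combine(cer, SULFATE)
    raise ValueError(f"unknown sphingolipid subclass {subclass!r}")


def make_sphingolipid(
    subclass: str,
    base_carbons: int,
    base_unsat: int,
    fa_carbons: int,
    fa_unsat: int,
    extra_fa_carbons: int = 0,
) -> LipidSpecies:
    formula = sphingolipid_formula(
        subclass, base_carbons, base_unsat, fa_carbons, fa_unsat, extra_fa_carbons
    )
    oxygens = 1 if subclass == "1-deoxyCer" else 2
    return LipidSpecies(
        lipid_class="sphingolipid",
        subclass=subclass,
        base_carbons=base_carbons,
        base_unsat=base_unsat,
        fa_carbons=fa_carbons,
        fa_unsat=fa_unsat,
        extra_fa_carbons=extra_fa_carbons,
        hydroxyl_count=oxygens,
        formula=dict(formula),
        mono_mass=monoisotopic_mass(formula),
        shorthand=compose_shorthand_sphingo(
            subclass, base_carbons, base_unsat, oxygens, fa_carbons, fa_unsat, extra_fa_carbons
        ),
    )


_GLYCERO_BACKBONES = {
    "PC": (GPC_BACKBONE, 2),
    "PE": (GPE_BACKBONE, 2),
    "PG": (GPG_BACKBONE, 2),
    "PI": (GPI_BACKBONE, 2),
    "betaine": (BETAINE_BACKBONE, 2),
    "TAG": (GLYCEROL, 3),
}

_CLASS_SHORTHAND = {
    "PC": "PC",
    "PE": "PE",
    "PG": "PG",
    "PI": "PI",
    "betaine": "DGTS",
    "TAG": "TG",
    "sterol": "ST",
    "alkenone": "Alkenone",
    "1G-DEG": "1G-DEG",
    "isoGDGT": "isoGDGT",
    "pigment": "Pigment",
}


def glycerolipid_formula(lipid_class: str, total_carbons: int, total_unsat: int) -> Counter:
    """Formula of a glycerolipid with summed acyl-chain descriptor."""
    backbone, n_acyl = _GLYCERO_BACKBONES[lipid_class]
    # all acyl carbons lumped into one FA plus (n_acyl-1) formal C2 units so
    # the ester count is right; algebraically identical to summing real chains
    out = Counter(backbone)
    out["C"] += total_carbons
    out["H"] += 2 * total_carbons - 2 * total_unsat - 2 * n_acyl
    out["O"] += n_acyl
    if any(v < 0 for v in out.values()):
        raise FormulaError(f"infeasible {lipid_class} {total_carbons}:{total_unsat}")
    return +out


def sterol_formula(carbons: int, unsat: int) -> Counter:
    return Counter({"C": carbons, "H": 2 * carbons - 2 * unsat, "O": 1})


def alkenone_formula(carbons: int, unsat: int) -> Counter:
    # long-chain methyl ketone; unsat counts C=C plus the carbonyl
    return Counter({"C": carbons, "H": 2 * carbons - 2 * unsat, "O": 1})


def deg_formula(total_carbons: int, total_unsat: int, glycosyl: bool = False) -> Counter:
    """Diether glycerolipid (DEG); optionally 1-glycosyl (1G-DEG)."""
    out = Counter(GLYCEROL)
    out["C"] += total_carbons
    out["H"] += 2 * total_carbons - 2 * total_unsat
    if glycosyl:
        out = combine(out, HEXOSE_RESIDUE)
    return +out


def isogdgt_formula(rings: int) -> Counter:
    return Counter({"C": 86, "H": 172 - 2 * rings, "O": 6})


def make_simple_lipid(lipid_class: str, total_carbons: int, total_unsat: int) -> LipidSpecies:
    """Non-sphingolipid species with a summed chain descriptor."""
    if lipid_class in _GLYCERO_BACKBONES:
        formula = glycerolipid_formula(lipid_class, total_carbons, total_unsat)
    elif lipid_class == "sterol":
        formula = sterol_formula(total_carbons, total_unsat)
    elif lipid_class == "alkenone":
        formula = alkenone_formula(total_carbons, total_unsat)
    elif lipid_class == "1G-DEG":
        formula = deg_formula(total_carbons, total_unsat, glycosyl=True)
    elif lipid_class == "isoGDGT":
        formula = isogdgt_formula(total_unsat)
    elif lipid_class == "pigment":
        formula = Counter(PHEOPHYTIN_A)
        formula["H"] -= 2 * total_unsat
    else:
        raise ValueError(f"no formula model for class {lipid_class!r}")
    tag = _CLASS_SHORTHAND[lipid_class]
    return LipidSpecies(
        lipid_class=lipid_class,
        fa_carbons=total_carbons,
        fa_unsat=total_unsat,
        hydroxyl_count=0,
        formula=dict(formula),
        mono_mass=monoisotopic_mass(formula),
        shorthand=f"{tag} {total_carbons}:{total_unsat}",
    )


# ---------------------------------------------------------------------------
# LIPID MAPS-style shorthand


def compose_shorthand_sphingo(
    subclass: str,
    base_carbons: int,
    base_unsat: int,
    base_oxygens: int,
    fa_carbons: int,
    fa_unsat: int,
    extra_fa_carbons: int = 0,
) -> str:
    name = f"{subclass} {base_carbons}:{base_unsat};O{base_oxygens}/{fa_carbons}:{fa_unsat}"
    if extra_fa_carbons:
        name += f"/{extra_fa_carbons}:0"
    return name


class ShorthandError(ValueError):
    """Unparseable shorthand name; carries the failing position."""

    def __init__(self, name: str, pos: int, why: str):
        super().__init__(f"cannot parse {name!r} at position {pos}: {why}")
        self.position = pos


def parse_shorthand(name: str) -> dict:
    """Parse shorthand like ``Cer 18:1;O2/24:0`` or ``PC 34:1`` to a descriptor.

    Returns a dict with keys lipid_class, subclass, base_carbons, base_unsat,
    base_oxygens, fa_carbons, fa_unsat, extra_fa_carbons. Sphingolipid names
    carry the sphingoid-base descriptor first; other classes a summed chain
    descriptor. ``TG 16:0_18:1_18:2`` style chain lists are summed.
    """
    name = name.strip()
    sp = name.find(" ")
    if sp <= 0:
        raise ShorthandError(name, max(sp, 0), "expected '<class> <chains>'")
    head, chains = name[:sp], name[sp + 1 :]
    if head in SPHINGO_SUBCLASSES:
        parts = chains.split("/")
        base = parts[0]
        if ";O" not in base:
            raise ShorthandError(name, sp + 1 + len(base.split(";")[0]), "missing ;O oxygen tag")
        cu, otag = base.split(";O")
        try:
            bc, bu = (int(x) for x in cu.split(":"))
            box = int(otag)
        except ValueError:
            raise ShorthandError(name, sp + 1, "bad sphingoid base descriptor") from None
        if len(parts) < 2:
            raise ShorthandError(name, len(name), "missing fatty acid descriptor")
        try:
            fc, fu = (int(x) for x in parts[1].split(":"))
        except ValueError:
            raise ShorthandError(name, name.find("/") + 1, "bad fatty acid descriptor") from None
        extra = 0
        if len(parts) == 3:
            try:
                extra = int(parts[2].split(":")[0])
            except ValueError:
                raise ShorthandError(name, name.rfind("/") + 1, "bad extra acyl descriptor") from None
        elif len(parts) > 3:
            raise ShorthandError(name, len(name), "too many chain fields")
        return {
            "lipid_class": "sphingolipid",
            "subclass": head,
            "base_carbons": bc,
            "base_unsat": bu,
            "base_oxygens": box,
            "fa_carbons": fc,
            "fa_unsat": fu,
            "extra_fa_carbons": extra,
        }
    rev = {v: k for k, v in _CLASS_SHORTHAND.items()}
    if head not in rev:
        raise ShorthandError(name, 0, f"unknown class tag {head!r}")
    tc = tu = 0
    for chain in chains.split("_"):
        try:
            c, u = (int(x) for x in chain.split(":"))
        except ValueError:
            raise ShorthandError(name, name.find(chain), "bad chain descriptor") from None
        tc += c
        tu += u
    return {
        "lipid_class": rev[head],
        "subclass": None,
        "base_carbons": 0,
        "base_unsat": 0,
        "base_oxygens": 0,
        "fa_carbons": tc,
        "fa_unsat": tu,
        "extra_fa_carbons": 0,
    }


def compose_shorthand(species: LipidSpecies) -> str:
    """Shorthand name of a species (inverse of :func:`parse_shorthand`)."""
    if species.lipid_class == "sphingolipid":
        return compose_shorthand_sphingo(
            species.subclass,
            species.base_carbons,
            species.base_unsat,
            species.hydroxyl_count,
            species.fa_carbons,
            species.fa_unsat,
            species.extra_fa_carbons,
        )
    tag = _CLASS_SHORTHAND[species.lipid_class]
    return f"{tag} {species.fa_carbons}:{species.fa_unsat}"


# ---------------------------------------------------------------------------
# shared fragment model (simulator <-> default rulebook)

#: Per-class constant diagnostics: ("frag", m/z) is a fragment ion observed
#: directly; ("loss", Da) a neutral loss observed at precursor - loss.
#: Chain-dependent diagnostics (sphingoid-base fragment, acyl losses) are
#: added programmatically by the simulator and rulebook.
CLASS_DIAGNOSTICS: dict[str, list[tuple[str, float]]] = {
    "sterol": [("loss", H2O), ("frag", 147.1168)],
    "TAG": [("frag", 99.0804), ("loss", H2O)],
    "PC": [("frag", FRAG_PHOSPHOCHOLINE), ("frag", 125.0004)],
    "PE": [("loss", 141.0191), ("frag", 62.0600)],
    "PG": [("loss", 172.0137), ("frag", 75.0269)],
    "PI": [("loss", 260.0297), ("frag", 85.0284)],
    "betaine": [("frag", 236.1492), ("frag", 144.1019)],
    "1G-DEG": [("loss", HEXOSE), ("frag", 117.0546)],
    "isoGDGT": [("loss", H2O), ("frag", 373.3672)],
    "alkenone": [("frag", 135.1168), ("loss", H2O)],
    "pigment": [("frag", 533.2689), ("loss", 278.2246)],
    # sphingolipid subclasses: subclass-diagnostic loss; the sphingoid-base
    # fragment is chain-dependent and added separately
    "Cer": [("loss", H2O)],
    "1-deoxyCer": [("loss", H2O)],
    "1-O-acylCer": [],  # extra-acyl loss added per candidate chain
    "Gly-Cer": [("loss", HEXOSE)],
    "Lysine-Cer": [("frag", FRAG_LYSINE)],
    "Sulfono-Cer": [("loss", LOSS_SULFONO)],
    "Sulfate-Cer": [("loss", LOSS_SULFATE_H2SO4), ("loss", LOSS_SULFATE_SO3)],
}

#: Class-specific base m/z for the 4-peak co-fragment ladder (spaced by CH2)
#: every simulated spectrum carries; gives same-class spectra direct matches
#: independent of chain length.
CLASS_LADDER_BASE: dict[str, float] = {
    "sterol": 81.0699,
    "TAG": 67.0542,
    "PC": 86.0964,
    "PE": 71.0730,
    "PG": 89.0597,
    "PI": 93.0700,
    "betaine": 100.0757,
    "1G-DEG": 97.0648,
    "isoGDGT": 111.1168,
    "alkenone": 95.0855,
    "pigment": 105.0699,
    "Cer": 60.0444,
    "1-deoxyCer": 58.0651,
    "1-O-acylCer": 64.0521,
    "Gly-Cer": 69.0340,
    "Lysine-Cer": 70.0651,
    "Sulfono-Cer": 73.0284,
    "Sulfate-Cer": 76.0216,
}


def sphingoid_base_fragment_mz(base_carbons: int, base_unsat: int, base_oxygens: int) -> float:
    """m/z of the dehydrated, protonated long-chain-base fragment.

    The dihydroxy base loses two waters (e.g. the classic m/z 264.2686 ion of
    an 18:1;O2 base); the 1-deoxy base loses one.
    """
    base = sphingoid_base(base_carbons, base_unsat, base_oxygens)
    n_h2o = 2 if base_oxygens >= 2 else 1
    return monoisotopic_mass(base) - n_h2o * H2O + PROTON
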