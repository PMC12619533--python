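"""Rule-based lipid annotation from accurate mass and diagnostic MS² evidence.

A rulebook entry covers one lipid class (or sphingolipid subclass): the
adducts it forms, a chain grid from which theoretical precursor masses are
enumerated, and the diagnostic evidence (constant fragment ions, neutral
losses, and chain-dependent ions such as the sphingoid-base fragment) whose
weighted presence fraction becomes the annotation score. Candidates whose
theoretical precursor matches the observed one within a ppm tolerance are
scored and ranked (score desc, |ppm| asc).

The default rulebook is generated from the same fragment table the
synthetic-spectrum simulator uses (:mod:`sedlipidomics.chem`), so annotation
is exercisable end-to-end against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import chem
from .chem import (
    LipidSpecies,
    adduct_mz,
    make_simple_lipid,
    make_sphingolipid,
    monoisotopic_mass,
)
from .spectra import Ms2Spectrum

DEFAULT_PPM_TOL = 5.0
DEFAULT_FRAG_TOL = 0.01
DEFAULT_SCORE_FLOOR = 0.5


@dataclass(frozen=True)
class AnnotationRule:
    """One class/subclass: adducts, chain grid, and diagnostic evidence."""

    name: str
    lipid_class: str
    subclass: str | None
    adducts: tuple[str, ...]
    diagnostics: tuple[tuple[str, float, float], ...]  # (kind, mz_or_loss, weight)
    chain_grid: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.diagnostics and not self.chain_grid.get("chain_evidence"):
            raise ValueError(f"rule {self.name}: at least one evidence item required")


@dataclass(frozen=True)
class LipidAnnotation:
    feature_id: str
    species: LipidSpecies
    adduct: str
    ppm: float
    score: float


class Rulebook:
    """A set of annotation rules with a precomputed candidate mass index."""

    def __init__(self, rules: Sequence[AnnotationRule]):
        if not rules:
            raise ValueError("empty rulebook")
        self.rules = list(rules)
        self._index = None

    def _candidates(self):
        """(sorted m/z array, parallel list of (rule, species, adduct))."""
        if self._index is None:
            mzs, refs = [], []
            for rule in self.rules:
                for sp in _enumerate_species(rule):
                    for adduct in rule.adducts:
                        mzs.append(adduct_mz(sp.mono_mass, adduct))
                        refs.append((rule, sp, adduct))
            order = np.argsort(mzs)
            self._index = (np.asarray(mzs)[order], [refs[i] for i in order])
        return self._index

    def to_yaml(self, path: str | Path) -> None:
        doc = [
            {
                "name": r.name,
                "lipid_class": r.lipid_class,
                "subclass": r.subclass,
                "adducts": list(r.adducts),
                "diagnostics": [list(d) for d in r.diagnostics],
                "chain_grid": r.chain_grid,
            }
            for r in self.rules
        ]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Rulebook":
        doc = yaml.safe_load(Path(path).read_text())
        rules = [
            AnnotationRule(
                name=r["name"],
                lipid_class=r["lipid_class"],
                subclass=r.get("subclass"),
                adducts=tuple(r["adducts"]),
                diagnostics=tuple((k, float(m), float(w)) for k, m, w in r["diagnostics"]),
                chain_grid=r.get("chain_grid", {}),
            )
            for r in doc
        ]
        return cls(rules)


def _enumerate_species(rule: AnnotationRule) -> list[LipidSpecies]:
    g = rule.chain_grid
    out: list[LipidSpecies] = []
    if rule.lipid_class == "sphingolipid":
        extra_range = g.get("extra_fa_carbons", [0])
        for b in _r(g["base_carbons"]):
            for ub in _r(g.get("base_unsat", [0, 1])):
                for f in _r(g["fa_carbons"]):
                    for uf in _r(g.get("fa_unsat", [0, 1, 2])):
                        for e in _r(extra_range):
                            out.append(
                                make_sphingolipid(rule.subclass, b, ub, f, uf, e)
                            )
    elif rule.lipid_class == "pigment":
        for u in _r(g.get("extra_unsat", [0, 1, 2])):
            out.append(make_simple_lipid("pigment", 55, u))
    elif rule.lipid_class == "isoGDGT":
        for rings in _r(g.get("rings", [0, 1, 2, 3, 4])):
            out.append(make_simple_lipid("isoGDGT", 86, rings))
    else:
        for c in _r(g["total_carbons"]):
            for u in _r(g.get("total_unsat", [0])):
                out.append(make_simple_lipid(rule.lipid_class, c, u))
    return out


def _r(spec) -> list[int]:
    if isinstance(spec, dict):
        return list(range(int(spec["min"]), int(spec["max"]) + 1))
    return [int(x) for x in spec]


# ---------------------------------------------------------------------------
# default rulebook (shares chem.CLASS_DIAGNOSTICS with the simulator)

_DEFAULT_GRIDS: dict[str, dict] = {
    "sterol": {"total_carbons": {"min": 27, "max": 30}, "total_unsat": [3, 4, 5]},
    "TAG": {"total_carbons": {"min": 42, "max": 66}, "total_unsat": [0, 1, 2, 3, 4, 5, 6]},
    "PC": {"total_carbons": {"min": 28, "max": 44}, "total_unsat": [0, 1, 2, 3, 4]},
    "PE": {"total_carbons": {"min": 28, "max": 44}, "total_unsat": [0, 1, 2, 3, 4]},
    "PG": {"total_carbons": {"min": 28, "max": 44}, "total_unsat": [0, 1, 2, 3, 4]},
    "PI": {"total_carbons": {"min": 28, "max": 44}, "total_unsat": [0, 1, 2, 3, 4]},
    "betaine": {"total_carbons": {"min": 28, "max": 40}, "total_unsat": [0, 1, 2, 3]},
    "1G-DEG": {"total_carbons": {"min": 28, "max": 44}, "total_unsat": [0, 1, 2, 3]},
    "isoGDGT": {"rings": [0, 1, 2, 3, 4]},
    "alkenone": {"total_carbons": {"min": 36, "max": 40}, "total_unsat": [2, 3, 4]},
    "pigment": {"extra_unsat": [0, 1, 2]},
}

_SPHINGO_GRID = {
    "base_carbons": {"min": 15, "max": 23},
    "base_unsat": [0, 1],
    "fa_carbons": {"min": 14, "max": 42},
    "fa_unsat": [0, 1, 2],
}

_ADDUCTS: dict[str, tuple[str, ...]] = {
    "sterol": ("[M+H-H2O]+", "[M+H]+", "[M+NH4]+", "[M+Na]+"),
    "TAG": ("[M+NH4]+", "[M+H]+"),
    "alkenone": ("[M+H]+", "[M+NH4]+"),
}


def default_rulebook() -> Rulebook:
    """Rulebook whose entries mirror the simulator's fragment model."""
    rules = []
    for cls, grid in _DEFAULT_GRIDS.items():
        diags = tuple((k, m, 1.0) for k, m in chem.CLASS_DIAGNOSTICS[cls])
        rules.append(
            AnnotationRule(
                name=cls,
                lipid_class=cls,
                subclass=None,
                adducts=_ADDUCTS.get(cls, ("[M+H]+",)),
                diagnostics=diags,
                chain_grid=grid,
            )
        )
    for sub in chem.SPHINGO_SUBCLASSES:
        grid = dict(_SPHINGO_GRID)
        grid["chain_evidence"] = True  # sphingoid-base fragment checked per candidate
        if sub == "1-O-acylCer":
            grid = {**grid, "extra_fa_carbons": {"min": 28, "max": 32}}
        diags = tuple((k, m, 1.0) for k, m in chem.CLASS_DIAGNOSTICS[sub])
        rules.append(
            AnnotationRule(
                name=sub,
                lipid_class="sphingolipid",
                subclass=sub,
                adducts=("[M+H]+",),
                diagnostics=diags,
                chain_grid=grid,
            )
        )
    return Rulebook(rules)


# ---------------------------------------------------------------------------
# scoring


def _has_peak(mzs: np.ndarray, target: float, tol: float) -> bool:
    i = np.searchsorted(mzs, target)
    for j in (i - 1, i):
        if 0 <= j < len(mzs) and abs(mzs[j] - target) <= tol:
            return True
    return False


def _candidate_evidence(rule: AnnotationRule, sp: LipidSpecies) -> list[tuple[str, float, float]]:
    """Constant diagnostics plus chain-dependent evidence for one candidate."""
    items = [(k, m, w) for k, m, w in rule.diagnostics]
    if rule.lipid_class == "sphingolipid":
        items.append(
            (
                "frag",
                chem.sphingoid_base_fragment_mz(sp.base_carbons, sp.base_unsat, sp.hydroxyl_count),
                1.0,
            )
        )
        if rule.subclass == "1-O-acylCer":
            items.append(("loss", monoisotopic_mass(chem.fatty_acid(sp.extra_fa_carbons, 0)), 1.0))
    return items


def annotate(
    spectrum: Ms2Spectrum,
    rulebook: Rulebook,
    ppm_tol: float = DEFAULT_PPM_TOL,
    frag_tol: float = DEFAULT_FRAG_TOL,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> list[LipidAnnotation]:
    """Rank candidate annotations for one spectrum.

    For every (rule, chain combination, adduct) whose theoretical precursor
    m/z matches the observed one within ``ppm_tol``, the score is the
    weighted fraction of diagnostic evidence found among the fragment peaks;
    candidates scoring at least ``score_floor`` are returned sorted by
    (score desc, |ppm| asc, name).
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    cand_mzs, cand_refs = rulebook._candidates()
    obs = spectrum.precursor_mz
    tol_da = obs * ppm_tol * 1e-6
    lo = np.searchsorted(cand_mzs, obs - tol_da, side="left")
    hi = np.searchsorted(cand_mzs, obs + tol_da, side="right")
    peaks = spectrum.mz
    hits = []
    for k in range(lo, hi):
        rule, sp, adduct = cand_refs[k]
        theo = cand_mzs[k]
        ppm = (obs - theo) / theo * 1e6
        items = _candidate_evidence(rule, sp)
        total = sum(w for _, _, w in items)
        got = 0.0
        for kind, m, w in items:
            target = m if kind == "frag" else obs - m
            if target > 0 and _has_peak(peaks, target, frag_tol):
                got += w
        score = got / total if total > 0 else 0.0
        if score >= score_floor:
            hits.append(LipidAnnotation(spectrum.feature_id, sp, adduct, ppm, score))
    hits.sort(key=lambda a: (-a.score, abs(a.ppm), a.species.shorthand, a.adduct))
    return hits


def annotate_spectra(
    spectra: Sequence[Ms2Spectrum],
    rulebook: Rulebook,
    ppm_tol: float = DEFAULT_PPM_TOL,
    frag_tol: float = DEFAULT_FRAG_TOL,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> dict[str, LipidAnnotation]:
    """Top-1 annotation per spectrum (features with no hit are omitted)."""
    out = {}
    for s in spectra:
        hits = annotate(s, rulebook, ppm_tol, frag_tol, score_floor)
        if hits:
            out[s.feature_id] = hits[0]
    return out


# ---------------------------------------------------------------------------
# sphingolipid subclass decision sequence


@dataclass(frozen=True)
class SphingoEvidence:
    """Observed evidence flags for a feature already typed as a sphingolipid."""

    is_sphingolipid: bool = True
    has_sulfate_loss: bool = False
    has_sulfono_loss: bool = False
    has_hexose_loss: bool = False
    has_lysine_fragment: bool = False
    extra_acyl_carbons: int | None = None  # C28-C32 long-chain acyl loss
    deoxy_shift: bool = False  # precursor -15.9949 vs same-descriptor Cer


def classify_sphingolipid_subclass(evidence: SphingoEvidence) -> str:
    """Assign one of the seven subclasses by a fixed decision sequence.

    Sulfate evidence wins over sulfono, then hexose (Gly-Cer), the lysine
    headgroup, an extra C28–C32 acyl loss (1-O-acylCer), the 1-deoxy mass
    shift, and finally the plain ceramide fall-through.
    """
    if not evidence.is_sphingolipid:
        raise ValueError("classify_sphingolipid_subclass requires sphingolipid evidence")
    if evidence.has_sulfate_loss:
        return "Sulfate-Cer"
    if evidence.has_sulfono_loss:
        return "Sulfono-Cer"
    if evidence.has_hexose_loss:
        return "Gly-Cer"
    if evidence.has_lysine_fragment:
        return "Lysine-Cer"
    if evidence.extra_acyl_carbons is not None:
        if not 28 <= evidence.extra_acyl_carbons <= 32:
            raise ValueError("extra acyl outside the C28-C32 window")
        return "1-O-acylCer"
    if evidence.deoxy_shift:
        return "1-deoxyCer"
    return "Cer"


def extract_sphingo_evidence(spectrum: Ms2Spectrum, frag_tol: float = DEFAULT_FRAG_TOL) -> SphingoEvidence:
    """Read subclass evidence flags off a sphingolipid MS² spectrum."""
    peaks = spectrum.mz
    obs = spectrum.precursor_mz

    def loss(m):
        return _has_peak(peaks, obs - m, frag_tol)

    extra = None
    for c in range(28, 33):
        if loss(monoisotopic_mass(chem.fatty_acid(c, 0))):
            extra = c
            break
    deoxy = False
    for b in range(15, 24):
        for ub in (0, 1):
            if _has_peak(peaks, chem.sphingoid_base_fragment_mz(b, ub, 1), frag_tol):
                deoxy = True
    return SphingoEvidence(
        has_sulfate_loss=loss(chem.LOSS_SULFATE_H2SO4) or loss(chem.LOSS_SULFATE_SO3),
        has_sulfono_loss=loss(chem.LOSS_SULFONO),
        has_hexose_loss=loss(chem.HEXOSE),
        has_lysine_fragment=_has_peak(peaks, chem.FRAG_LYSINE, frag_tol),
        extra_acyl_carbons=extra,
        deoxy_shift=deoxy,
    )


# ---------------------------------------------------------------------------
# homolog series


def detect_analog_series(
    features: Sequence[tuple[str, float]],
    gaps: dict[str, float] | None = None,
    tol: float = 0.01,
) -> list[dict]:
    """Find maximal homolog series among features by characteristic mass gaps.

    ``features`` are (feature_id, neutral-or-precursor mass) pairs. For each
    gap type (CH2, H2, O, hexose by default) the features are chained along
    edges whose mass difference is an exact multiple-free single gap within
    ``tol``; connected runs of ≥2 members form one series. A feature may
    appear in several series.
    """
    gaps = gaps or chem.SERIES_GAPS
    ordered = sorted(features, key=lambda f: (f[1], f[0]))
    out = []
    for gap_name, gap in sorted(gaps.items()):
        parent = list(range(len(ordered)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                d = ordered[j][1] - ordered[i][1]
                if d > gap + tol:
                    break
                if abs(d - gap) <= tol:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list[str]] = {}
        for i in range(len(ordered)):
            groups.setdefault(find(i), []).append(ordered[i][0])
        for members in groups.values():
            if len(members) >= 2:
                out.append({"gap": gap_name, "members": members})
    out.sort(key=lambda s: (s["gap"], s["members"]))
    return out


def annotations_to_frame(annotations: dict[str, LipidAnnotation]):
    """Annotations as a tidy DataFrame (feature_id, class, subclass, ...)."""
    import pandas as pd

    rows = [
        {
            "feature_id": fid,
            "lipid_class": a.species.lipid_class,
            "subclass": a.species.subclass or "",
            "shorthand": a.species.shorthand,
            "adduct": a.adduct,
            "ppm": a.ppm,
            "score": a.score,
        }
        for fid, a in sorted(annotations.items())
    ]
    return pd.DataFrame(rows)
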