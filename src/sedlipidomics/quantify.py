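"""Semi-quantification via class-specific single-point response factors.

Peak areas are converted to amounts with one response factor (RF = area per
ng) per lipid class, resolved through a fallback chain (own standard →
class standard → configured proxy class → average of all standards), after
normalising each sample by its internal deuterated betaine standard
(DGTS-d9). Water-column samples report ng L⁻¹ of filtered water; sediment
samples ng g⁻¹ TOC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import LipidAnnotation
from .spectra import sample_columns


@dataclass(frozen=True)
class ResponseFactor:
    key: str  # class or subclass label
    rf: float  # area per ng
    source: str  # own-standard | proxy-class | class-average | global-average
    standard_name: str

    def __post_init__(self):
        if not self.rf > 0:
            raise ValueError(f"response factor must be positive, got {self.rf}")


def fit_response_factor(
    standard_areas: Sequence[float],
    standard_amounts: Sequence[float],
    key: str = "",
    standard_name: str = "",
) -> ResponseFactor:
    """Single-point RF: mean(area/amount) over one or more injections.

    A standards mix (e.g. a ceramide mix) contributes the mean of its
    members' individual RFs, matching a line through the origin per member.
    """
    areas = np.asarray(standard_areas, dtype=float)
    amounts = np.asarray(standard_amounts, dtype=float)
    if areas.size == 0 or areas.size != amounts.size:
        raise ValueError("need equal, non-zero numbers of areas and amounts")
    if (amounts <= 0).any():
        raise ValueError("standard amounts must be positive")
    rf = float(np.mean(areas / amounts))
    src = "own-standard" if areas.size == 1 else "class-average"
    return ResponseFactor(key, rf, src, standard_name)


def fit_standards_table(standards: pd.DataFrame) -> dict[str, ResponseFactor]:
    """RFs per class key from a standards table (key, standard_name, area, amount)."""
    out = {}
    for key, grp in standards.groupby("key", sort=True):
        out[key] = fit_response_factor(
            grp["area"].to_list(),
            grp["amount"].to_list(),
            key=key,
            standard_name=";".join(grp["standard_name"].astype(str)),
        )
    return out


def resolve_response_factor(
    lipid_class: str,
    subclass: str | None,
    rf_table: Mapping[str, ResponseFactor],
    proxy_map: Mapping[str, str] | None = None,
) -> ResponseFactor:
    """Resolve the RF for a species through the fallback chain.

    Order: exact subclass standard → class standard → configured proxy class
    (e.g. ornithine lipids borrowing the DGTS betaine RF) → arithmetic mean
    of all external standards. The chosen source is recorded.
    """
    if not rf_table:
        raise ValueError("empty response-factor table")
    if subclass and subclass in rf_table:
        return rf_table[subclass]
    if lipid_class in rf_table:
        return rf_table[lipid_class]
    proxy_map = proxy_map or {}
    for key in (subclass, lipid_class):
        if key and key in proxy_map and proxy_map[key] in rf_table:
            p = rf_table[proxy_map[key]]
            return ResponseFactor(key, p.rf, "proxy-class", p.standard_name)
    mean_rf = float(np.mean([r.rf for r in rf_table.values()]))
    return ResponseFactor(subclass or lipid_class, mean_rf, "global-average", "all-standards")


def summed_adduct_area(feature_group: Sequence[tuple[str, float]]) -> float:
    """Total area of one species' adduct features ([M+H]+ etc.).

    ``feature_group`` is (adduct, area) pairs; a repeated adduct within the
    group signals a conflicting assignment and raises.
    """
    seen = set()
    total = 0.0
    for adduct, area in feature_group:
        if adduct in seen:
            raise ValueError(f"conflicting adduct assignment: {adduct} appears twice")
        seen.add(adduct)
        total += float(area)
    return total


def quantify(
    feature_table: pd.DataFrame,
    annotations: Mapping[str, LipidAnnotation],
    rf_table: Mapping[str, ResponseFactor],
    internal_std: str,
    metadata: pd.DataFrame,
    proxy_map: Mapping[str, str] | None = None,
    dry_mass_g: float | Mapping[str, float] = 1.0,
) -> pd.DataFrame:
    """Species × sample concentrations in matrix-appropriate units.

    Per sample s and species i: amount = (area / RF_i) × (expected IS area /
    observed IS area in s), with the expected IS area taken as the mean
    observed IS area across samples. Adduct features annotated to the same
    species are summed before calibration. Water samples divide by filtered
    volume (ng L⁻¹); sediment samples by dry mass × TOC fraction
    (ng g⁻¹ TOC). The result carries the species rows, sample columns, and
    a ``units`` column.
    """
    samples = sample_columns(feature_table)
    meta = metadata.set_index(metadata["sample_id"].astype(str))
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")
    if internal_std not in feature_table.index:
        raise ValueError(f"internal standard feature {internal_std!r} not in table")
    is_areas = feature_table.loc[internal_std, samples].astype(float)
    bad = [s for s in samples if not is_areas[s] > 0]
    if bad:
        raise ValueError(f"internal standard missing (zero area) in sample(s): {bad}")
    is_factor = float(is_areas.mean()) / is_areas  # expected / observed

    # group features by annotated species, summing adduct areas
    by_species: dict[str, dict] = {}
    for fid, ann in annotations.items():
        if fid == internal_std or fid not in feature_table.index:
            continue
        rec = by_species.setdefault(
            ann.species.shorthand,
            {"species": ann.species, "features": []},
        )
        rec["features"].append((ann.adduct, fid, ann.score, abs(ann.ppm)))

    rows = []
    for shorthand in sorted(by_species):
        rec = by_species[shorthand]
        sp = rec["species"]
        rf = resolve_response_factor(sp.lipid_class, sp.subclass, rf_table, proxy_map)
        # features claiming the same adduct cannot be one species' adduct set;
        # such ties (isomers / ambiguous annotations) become separate rows,
        # with the best-scoring evidence kept under the canonical name
        subgroups: list[dict[str, str]] = []
        for adduct, fid, score, absppm in sorted(
            rec["features"], key=lambda t: (-t[2], t[3], t[1])
        ):
            for g in subgroups:
                if adduct not in g:
                    g[adduct] = fid
                    break
            else:
                subgroups.append({adduct: fid})
        for gi, group in enumerate(subgroups):
            area = pd.Series(0.0, index=samples)
            for adduct, fid in group.items():
                area = area + feature_table.loc[fid, samples].astype(float)
            amount_ng = (area / rf.rf) * is_factor
            _append_row(
                rows, shorthand if gi == 0 else f"{shorthand}#{gi + 1}", sp, rf,
                amount_ng, samples, meta, dry_mass_g,
            )
    out = pd.DataFrame(rows).set_index("shorthand") if rows else pd.DataFrame(
        columns=["lipid_class", "subclass", "rf_source", *samples]
    )
    units = {
        s: ("ng/L" if meta.loc[s, "matrix"] == "water" else "ng/g TOC") for s in samples
    }
    out.attrs["units"] = units
    return out


def _append_row(rows, label, sp, rf, amount_ng, samples, meta, dry_mass_g):
    conc = {}
    for s in samples:
        m = meta.loc[s]
        if m["matrix"] == "water":
            conc[s] = amount_ng[s] / float(m["filtered_volume"])
        else:
            dm = dry_mass_g[s] if isinstance(dry_mass_g, Mapping) else dry_mass_g
            conc[s] = amount_ng[s] / (float(dm) * float(m["toc_fraction"]))
    rows.append(
        {
            "shorthand": label,
            "lipid_class": sp.lipid_class,
            "subclass": sp.subclass or "",
            "rf_source": rf.source,
            **conc,
        }
    )


def format_amount(ng: float) -> str:
    """Report ng values, switching to µg above 1000 ng."""
    if ng >= 1000.0:
        return f"{ng / 1000.0:.3g} ug"
    return f"{ng:.3g} ng"
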