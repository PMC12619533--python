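"""Seeded synthetic lipidome generator with full ground truth.

The generator emulates a stratified-basin study design: a water column with
oxic, suboxic and euxinic depths and a sediment core spanning marine,
transitional and lacustrine phases. It draws a species catalog (seven
sphingolipid subclasses plus sterols, TAGs, phospholipids, betaine lipids,
glycolipids, isoGDGTs, alkenones and a pigment proxy), zone-structured
abundance profiles (sterol-dominated oxic surface water, phospholipid-rich
euxinic water, sphingolipid-rich sediments), per-class ionization response
distortion, and MS² spectra whose fragments follow the same stylized model
the default annotation rulebook encodes.

Everything the downstream pipeline estimates (species identities,
abundances, response factors) is recorded in :class:`SyntheticTruth` so
recovery can be tested without consulting hidden state.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem
from .chem import LipidSpecies, adduct_mz, make_simple_lipid, make_sphingolipid
from .quantify import ResponseFactor, resolve_response_factor
from .spectra import Ms2Spectrum, Peak, write_feature_table, write_mgf

#: species counts for the seven sphingolipid subclasses (catalog defaults)
DEFAULT_SPHINGO_COUNTS = {
    "Cer": 112,
    "1-deoxyCer": 73,
    "1-O-acylCer": 57,
    "Gly-Cer": 10,
    "Lysine-Cer": 6,
    "Sulfono-Cer": 41,
    "Sulfate-Cer": 18,
}

DEFAULT_OTHER_COUNTS = {
    "sterol": 10,
    "TAG": 10,
    "pigment": 3,
    "PC": 8,
    "PE": 8,
    "PG": 6,
    "PI": 6,
    "betaine": 4,
    "1G-DEG": 4,
    "isoGDGT": 3,
    "alkenone": 5,
}

#: per-zone mean class fractions of total quantified lipids (sum to 1)
DEFAULT_ZONE_TARGETS: dict[str, dict[str, float]] = {
    "oxic": {
        "sterol": 0.63, "TAG": 0.15, "alkenone": 0.03, "pigment": 0.10,
        "PC": 0.030, "PE": 0.020, "PG": 0.010, "PI": 0.005,
        "betaine": 0.015, "1G-DEG": 0.003, "isoGDGT": 0.005, "sphingolipid": 0.002,
    },
    "suboxic": {
        "sterol": 0.16, "TAG": 0.55, "alkenone": 0.03, "pigment": 0.10,
        "PC": 0.045, "PE": 0.035, "PG": 0.020, "PI": 0.010,
        "betaine": 0.030, "1G-DEG": 0.005, "isoGDGT": 0.013, "sphingolipid": 0.002,
    },
    "euxinic": {
        "sterol": 0.30, "TAG": 0.07, "alkenone": 0.02, "pigment": 0.10,
        "PC": 0.08, "PE": 0.12, "PG": 0.06, "PI": 0.04,
        "betaine": 0.05, "1G-DEG": 0.03, "isoGDGT": 0.08, "sphingolipid": 0.05,
    },
    "marine": {
        "sterol": 0.31, "TAG": 0.02, "alkenone": 0.08, "pigment": 0.21,
        "PC": 0.0003, "PE": 0.0003, "PG": 0.0002, "PI": 0.0002,
        "betaine": 0.005, "1G-DEG": 0.03, "isoGDGT": 0.064, "sphingolipid": 0.28,
    },
    "transitional": {
        "sterol": 0.40, "TAG": 0.03, "alkenone": 0.05, "pigment": 0.18,
        "PC": 0.0003, "PE": 0.0003, "PG": 0.0002, "PI": 0.0002,
        "betaine": 0.005, "1G-DEG": 0.03, "isoGDGT": 0.064, "sphingolipid": 0.24,
    },
    "lacustrine": {
        "sterol": 0.56, "TAG": 0.05, "alkenone": 0.05, "pigment": 0.04,
        "PC": 0.0003, "PE": 0.0003, "PG": 0.0002, "PI": 0.0002,
        "betaine": 0.004, "1G-DEG": 0.04, "isoGDGT": 0.105, "sphingolipid": 0.15,
    },
}

#: default sample layout: (sample_id, matrix, depth, unit, zone, toc, volume)
DEFAULT_SAMPLES = [
    ("W050", "water", 50, "mbsl", "oxic", None, 200.0),
    ("W090", "water", 90, "mbsl", "suboxic", None, 200.0),
    ("W500", "water", 500, "mbsl", "euxinic", None, 250.0),
    ("W1000", "water", 1000, "mbsl", "euxinic", None, 250.0),
    ("W1500", "water", 1500, "mbsl", "euxinic", None, 300.0),
    ("W2000", "water", 2000, "mbsl", "euxinic", None, 300.0),
    ("S020", "sediment", 20, "cmbsf", "marine", 0.060, None),
    ("S050", "sediment", 50, "cmbsf", "marine", 0.055, None),
    ("S080", "sediment", 80, "cmbsf", "marine", 0.050, None),
    ("S105", "sediment", 105, "cmbsf", "transitional", 0.030, None),
    ("S115", "sediment", 115, "cmbsf", "transitional", 0.028, None),
    ("S130", "sediment", 130, "cmbsf", "transitional", 0.025, None),
    ("S150", "sediment", 150, "cmbsf", "lacustrine", 0.012, None),
    ("S180", "sediment", 180, "cmbsf", "lacustrine", 0.010, None),
    ("S210", "sediment", 210, "cmbsf", "lacustrine", 0.008, None),
]

#: sterol-type classes whose signal splits over the four positive adducts
STEROL_ADDUCT_SPLIT = {"[M+H-H2O]+": 0.65, "[M+H]+": 0.20, "[M+NH4]+": 0.10, "[M+Na]+": 0.05}

INTERNAL_STD_ID = "IS_DGTS_d9"
_D_SHIFT = 9 * 1.006277  # nine H -> D substitutions

RF_PROXY_MAP = {"1G-DEG": "betaine", "isoGDGT": "TAG"}

#: standards mix composition: rf key -> list of (standard name, rf multiplier)
STANDARDS_MIXES: dict[str, list[tuple[str, float]]] = {
    "sterol": [
        ("Epicoprostanol", 0.90), ("Coprostanol", 0.95), ("Cholesterol", 1.00),
        ("Stigmasterol", 1.05), ("beta-Sitosterol", 1.10),
    ],
    "sphingolipid": [("Cer mix A", 0.80), ("Cer mix B", 1.20)],
    "1-deoxyCer": [("1-deoxyCer(d18:1/24:0)", 1.00)],
    "Gly-Cer": [("Glucosyl(beta) C12 Cer", 1.00)],
    "TAG": [("tripalmitin", 1.00)],
    "PC": [("PC standard", 1.00)],
    "PE": [("PE standard", 1.00)],
    "PG": [("PG standard", 1.00)],
    "PI": [("PI standard", 1.00)],
    "betaine": [("DGTS standard", 1.00)],
    "pigment": [("chlorophyll a (as pheophytin a)", 1.00)],
    "alkenone": [("C37:2 alkenone", 1.00)],
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic lipidome; defaults are the study conditions."""

    seed: int = 42
    sphingo_counts: dict = field(default_factory=lambda: dict(DEFAULT_SPHINGO_COUNTS))
    other_counts: dict = field(default_factory=lambda: dict(DEFAULT_OTHER_COUNTS))
    base_carbon_range: tuple[int, int] = (15, 23)
    fa_carbon_range: tuple[int, int] = (14, 42)
    extra_fa_range: tuple[int, int] = (28, 32)
    zone_targets: dict = field(default_factory=lambda: {z: dict(t) for z, t in DEFAULT_ZONE_TARGETS.items()})
    samples: tuple = tuple(DEFAULT_SAMPLES)
    total_lipid_ng: dict = field(default_factory=lambda: {"water": 2000.0, "sediment": 50000.0})
    # noise model
    class_fraction_sd: float = 0.05  # between-sample lognormal sd on zone targets
    area_noise_sd: float = 0.01  # measurement-level multiplicative sd on areas
    intensity_jitter_sd: float = 0.25  # fragment intensity pattern variation
    fragment_dropout: float = 0.05
    mz_jitter_sd: float = 0.002  # Da, fragments
    precursor_jitter_sd: float = 0.0005  # Da
    noise_peak_rate: float = 2.0  # Poisson count of junk peaks per spectrum
    rf_log_sd: float = 0.5  # per-class response distortion, lognormal around 1
    # water/sediment sphingolipid partition (Fig-2D-like structure)
    sediment_exclusive_fraction: float = 0.69
    shared_fraction: float = 0.09
    internal_std_area: float = 50000.0

    def noise_free(self) -> "GeneratorConfig":
        return replace(
            self,
            class_fraction_sd=0.0,
            area_noise_sd=0.0,
            intensity_jitter_sd=0.0,
            fragment_dropout=0.0,
            mz_jitter_sd=0.0,
            precursor_jitter_sd=0.0,
            noise_peak_rate=0.0,
        )

    def small(self) -> "GeneratorConfig":
        """A reduced catalog (≈1/4 scale, same structure) for quick runs."""
        sph = {k: max(2, v // 4) for k, v in self.sphingo_counts.items()}
        oth = {k: max(2, v // 2) for k, v in self.other_counts.items()}
        return replace(self, sphingo_counts=sph, other_counts=oth)


@dataclass
class SyntheticTruth:
    catalog: list[LipidSpecies]
    abundance: pd.DataFrame  # shorthand x samples, ng
    response_factors: dict[str, float]  # rf key -> area per ng
    feature_species: dict[str, tuple[str, str]]  # feature id -> (shorthand, adduct)
    water_species: set[str]
    sediment_species: set[str]
    zone_of: dict[str, str]


@dataclass
class SyntheticBundle:
    spectra: list[Ms2Spectrum]
    feature_table: pd.DataFrame
    metadata: pd.DataFrame
    standards: pd.DataFrame
    truth: SyntheticTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# catalog


def generate_species_catalog(config: GeneratorConfig) -> list[LipidSpecies]:
    """Draw the species catalog; chain descriptors uniform over configured ranges.

    Both odd and even fatty-acid carbon numbers occur (the bacterial odd-chain
    signature); duplicate chain descriptors are re-drawn so counts are exact.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    b_lo, b_hi = config.base_carbon_range
    f_lo, f_hi = config.fa_carbon_range
    e_lo, e_hi = config.extra_fa_range
    if b_lo > b_hi or f_lo > f_hi or e_lo > e_hi:
        raise ValueError("infeasible chain range")
    catalog: list[LipidSpecies] = []
    for sub in chem.SPHINGO_SUBCLASSES:
        n = int(config.sphingo_counts.get(sub, 0))
        f_hi_sub = min(f_hi, 16) if sub == "1-O-acylCer" else f_hi  # shorter chains, as for 1-O-acyl cores
        seen = set()
        made = 0
        while made < n:
            b = int(rng.integers(b_lo, b_hi + 1))
            ub = int(rng.integers(0, 2))
            f = int(rng.integers(f_lo, f_hi_sub + 1))
            uf = int(rng.integers(0, 3))
            e = int(rng.integers(e_lo, e_hi + 1)) if sub == "1-O-acylCer" else 0
            key = (b, ub, f, uf, e)
            if key in seen:
                continue
            seen.add(key)
            catalog.append(make_sphingolipid(sub, b, ub, f, uf, e))
            made += 1
    grids = {
        "sterol": [(c, u) for c in range(27, 31) for u in (3, 4, 5)],
        "TAG": [(c, u) for c in range(42, 67, 2) for u in range(0, 7)],
        "pigment": [(55, u) for u in (0, 1, 2)],
        "PC": [(c, u) for c in range(28, 45, 2) for u in range(0, 5)],
        "PE": [(c, u) for c in range(28, 45, 2) for u in range(0, 5)],
        "PG": [(c, u) for c in range(28, 45, 2) for u in range(0, 5)],
        "PI": [(c, u) for c in range(28, 45, 2) for u in range(0, 5)],
        "betaine": [(c, u) for c in range(28, 41, 2) for u in range(0, 4)],
        "1G-DEG": [(c, u) for c in range(28, 45, 2) for u in range(0, 4)],
        "isoGDGT": [(86, r) for r in range(0, 5)],
        "alkenone": [(c, u) for c in range(36, 41) for u in (2, 3, 4)],
    }
    for cls, n in config.other_counts.items():
        options = grids[cls]
        idx = rng.choice(len(options), size=min(int(n), len(options)), replace=False)
        for i in sorted(idx):
            c, u = options[i]
            catalog.append(make_simple_lipid(cls, c, u))
    return catalog


# ---------------------------------------------------------------------------
# abundance profiles


def _species_class_key(sp: LipidSpecies) -> str:
    return sp.subclass if sp.lipid_class == "sphingolipid" else sp.lipid_class


def simulate_profiles(
    catalog: Sequence[LipidSpecies],
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """True abundance matrix (ng) for the configured sample layout.

    Per sample, zone-target class fractions are perturbed by lognormal noise
    (sd ``class_fraction_sd``) and renormalised; within a class, species
    weights come from one Dirichlet(1) draw per (class, matrix), so water
    and sediment communities differ in species makeup. A configured fraction
    of sphingolipid species is sediment-exclusive (zeroed in water), a small
    fraction shared, and the remainder water-exclusive, mirroring the strong
    water/sediment partition of sphingolipid species.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    samples = list(config.samples)
    for sid, matrix, depth, unit, zone, toc, vol in samples:
        if zone not in config.zone_targets:
            raise ValueError(f"sample {sid}: no zone target for {zone!r}")

    sphingos = [sp.shorthand for sp in catalog if sp.lipid_class == "sphingolipid"]
    n_sph = len(sphingos)
    order = rng.permutation(n_sph)
    n_sed = int(round(config.sediment_exclusive_fraction * n_sph))
    n_shared = int(round(config.shared_fraction * n_sph))
    sed_only = {sphingos[i] for i in order[:n_sed]}
    shared = {sphingos[i] for i in order[n_sed : n_sed + n_shared]}
    water_only = set(sphingos) - sed_only - shared
    water_sph = shared | water_only
    sed_sph = shared | sed_only

    classes = sorted({_species_class_key(sp) for sp in catalog})
    members: dict[str, list[str]] = {c: [] for c in classes}
    for sp in catalog:
        members[_species_class_key(sp)].append(sp.shorthand)

    # one within-class composition draw per (class, matrix)
    weights: dict[tuple[str, str], pd.Series] = {}
    for cls in classes:
        for matrix in ("water", "sediment"):
            names = members[cls]
            w = rng.dirichlet(np.ones(len(names)))
            s = pd.Series(w, index=names)
            if cls in chem.SPHINGO_SUBCLASSES:
                allowed = water_sph if matrix == "water" else sed_sph
                s[~s.index.isin(allowed)] = 0.0
                if s.sum() > 0:
                    s = s / s.sum()
            weights[(cls, matrix)] = s

    cols = {}
    for sid, matrix, depth, unit, zone, toc, vol in samples:
        targets = config.zone_targets[zone]
        class_frac = {}
        for cls_name, target in sorted(targets.items()):
            noise = np.exp(rng.normal(0.0, config.class_fraction_sd)) if config.class_fraction_sd > 0 else 1.0
            class_frac[cls_name] = target * noise
        total = sum(class_frac.values())
        class_frac = {k: v / total for k, v in class_frac.items()}
        total_ng = config.total_lipid_ng[matrix]
        col = pd.Series(0.0, index=[sp.shorthand for sp in catalog])
        # class budgets: the sphingolipid target covers all seven subclasses
        # jointly, split by how many subclass species occur in this matrix
        sub_budget = {}
        n_sub_species = {c: (weights[(c, matrix)] > 0).sum() for c in classes if c in chem.SPHINGO_SUBCLASSES}
        tot_present = sum(n_sub_species.values())
        for c in classes:
            if c in chem.SPHINGO_SUBCLASSES:
                sub_budget[c] = (
                    class_frac.get("sphingolipid", 0.0) * n_sub_species[c] / tot_present
                    if tot_present
                    else 0.0
                )
            else:
                sub_budget[c] = class_frac.get(c, 0.0)
        for cls in classes:
            ng = total_ng * sub_budget.get(cls, 0.0)
            w = weights[(cls, matrix)]
            col.loc[w.index] += ng * w.to_numpy()
        cols[sid] = col
    abundance = pd.DataFrame(cols)
    return abundance, water_sph, sed_sph


# ---------------------------------------------------------------------------
# spectra


def _spectrum_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF])
    )


def primary_adduct(sp: LipidSpecies) -> str:
    return "[M+H-H2O]+" if sp.lipid_class == "sterol" else "[M+H]+"


def simulate_ms2(
    species: LipidSpecies,
    config: GeneratorConfig,
    adduct: str | None = None,
    feature_id: str | None = None,
    retention_time: float | None = None,
) -> Ms2Spectrum:
    """Deterministic synthetic MS² spectrum for one species and adduct.

    Peaks: the class-diagnostic fragments and neutral losses of the shared
    fragment model, a six-peak CH2-spaced co-fragment ladder whose intensity
    pattern shifts smoothly with chain length (so chain-near homologs look
    more alike), the sphingoid-base fragment for sphingolipids, and Poisson
    noise peaks. Fragment m/z are jittered and peaks dropped per the noise
    model. Identical (seed, species, adduct) always yields the same spectrum.
    """
    adduct = adduct or primary_adduct(species)
    rng = _spectrum_rng(config.seed, f"{species.shorthand}|{adduct}")
    prec = adduct_mz(species.mono_mass, adduct)
    key = _species_class_key(species)

    peaks: list[tuple[float, float]] = []
    for kind, m in chem.CLASS_DIAGNOSTICS[key]:
        mz = m if kind == "frag" else prec - m
        if mz > 0:
            peaks.append((mz, 100.0))
    if species.lipid_class == "sphingolipid":
        peaks.append(
            (
                chem.sphingoid_base_fragment_mz(
                    species.base_carbons, species.base_unsat, species.hydroxyl_count
                ),
                80.0,
            )
        )
        if species.subclass == "1-O-acylCer":
            peaks.append((prec - chem.monoisotopic_mass(chem.fatty_acid(species.extra_fa_carbons, 0)), 90.0))
    # chain-dependent ladder
    totc = species.base_carbons + species.fa_carbons + species.extra_fa_carbons
    t = np.clip((totc - 28) / 45.0, 0.0, 1.0)
    base_mz = chem.CLASS_LADDER_BASE[key]
    for k in range(6):
        w = float(np.exp(-((k / 5.0 - t) ** 2) / (2 * 0.2**2)))
        peaks.append((base_mz + k * chem.CH2, 20.0 + 60.0 * w))

    out: list[Peak] = []
    for mz, inten in peaks:
        if config.fragment_dropout > 0 and rng.random() < config.fragment_dropout:
            continue
        jmz = mz + (rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd > 0 else 0.0)
        jint = inten * (
            np.exp(rng.normal(0.0, config.intensity_jitter_sd)) if config.intensity_jitter_sd > 0 else 1.0
        )
        if jmz > 0:
            out.append(Peak(jmz, float(jint)))
    n_noise = int(rng.poisson(config.noise_peak_rate)) if config.noise_peak_rate > 0 else 0
    for _ in range(n_noise):
        out.append(Peak(float(rng.uniform(60.0, max(80.0, prec - 1))), float(rng.uniform(1.0, 6.0))))
    if not out:  # dropout removed everything; keep the strongest diagnostic
        out = [Peak(peaks[0][0], peaks[0][1])]
    jprec = prec + (rng.normal(0.0, config.precursor_jitter_sd) if config.precursor_jitter_sd > 0 else 0.0)
    rt = retention_time if retention_time is not None else _retention_time(species)
    return Ms2Spectrum(feature_id or species.shorthand, float(jprec), rt, tuple(out))


def _retention_time(species: LipidSpecies) -> float:
    """Stylized reversed-phase RT in minutes, increasing with mass."""
    return round(5.0 + 60.0 * (species.mono_mass - 300.0) / 1700.0, 3)


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: GeneratorConfig = GeneratorConfig()) -> SyntheticBundle:
    """Generate the full bundle: spectra, feature table, metadata, standards, truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    catalog = generate_species_catalog(config)
    abundance, water_sph, sed_sph = simulate_profiles(catalog, config)
    samples = list(config.samples)
    sample_ids = [s[0] for s in samples]

    metadata = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "matrix": matrix,
                "depth": depth,
                "depth_unit": unit,
                "zone": zone,
                "toc_fraction": toc if toc is not None else "",
                "filtered_volume": vol if vol is not None else "",
            }
            for sid, matrix, depth, unit, zone, toc, vol in samples
        ]
    )

    # hidden per-class response distortion, keyed like the standards table
    rf_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    rf_truth = {
        key: float(100.0 * np.exp(rf_rng.normal(0.0, config.rf_log_sd)))
        for key in sorted(STANDARDS_MIXES)
    }
    rf_table = {
        k: ResponseFactor(k, v, "own-standard", "truth") for k, v in rf_truth.items()
    }

    by_short = {sp.shorthand: sp for sp in catalog}
    spectra: list[Ms2Spectrum] = []
    feature_rows = []
    feature_species: dict[str, tuple[str, str]] = {}
    fid_counter = 0
    for sp in catalog:
        rf = resolve_response_factor(sp.lipid_class, sp.subclass, rf_table, RF_PROXY_MAP).rf
        adducts = (
            list(STEROL_ADDUCT_SPLIT.items()) if sp.lipid_class == "sterol" else [(primary_adduct(sp), 1.0)]
        )
        rt = _retention_time(sp)
        for adduct, split in adducts:
            fid_counter += 1
            fid = f"F{fid_counter:05d}"
            spec = simulate_ms2(sp, config, adduct=adduct, feature_id=fid, retention_time=rt)
            spectra.append(spec)
            feature_species[fid] = (sp.shorthand, adduct)
            areas = {}
            for sid in sample_ids:
                ng = abundance.loc[sp.shorthand, sid]
                noise = (
                    np.exp(rng.normal(0.0, config.area_noise_sd)) if config.area_noise_sd > 0 else 1.0
                )
                areas[sid] = ng * rf * split * noise
            feature_rows.append({"feature_id": fid, "mz": spec.precursor_mz, "rt": rt, **areas})

    # internal standard present in every sample
    is_mass = chem.monoisotopic_mass(chem.glycerolipid_formula("betaine", 32, 0)) + _D_SHIFT
    is_areas = {
        sid: config.internal_std_area
        * (np.exp(rng.normal(0.0, config.area_noise_sd)) if config.area_noise_sd > 0 else 1.0)
        for sid in sample_ids
    }
    feature_rows.append(
        {"feature_id": INTERNAL_STD_ID, "mz": adduct_mz(is_mass, "[M+H]+"), "rt": 38.0, **is_areas}
    )
    feature_table = pd.DataFrame(feature_rows).set_index("feature_id")

    # external standard injections: areas consistent with the hidden rfs
    std_rows = []
    for key in sorted(STANDARDS_MIXES):
        for name, mult in STANDARDS_MIXES[key]:
            amount = 10.0
            std_rows.append(
                {
                    "key": key,
                    "standard_name": name,
                    "amount": amount,
                    "area": rf_truth[key] * mult * amount,
                }
            )
    standards = pd.DataFrame(std_rows)

    zone_of = {s[0]: s[4] for s in samples}
    truth = SyntheticTruth(
        catalog=catalog,
        abundance=abundance,
        response_factors=rf_truth,
        feature_species=feature_species,
        water_species=water_sph,
        sediment_species=sed_sph,
        zone_of=zone_of,
    )
    return SyntheticBundle(spectra, feature_table, metadata, standards, truth, config)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Persist the bundle in the formats the pipeline reads; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mgf": out / "spectra.mgf",
        "features": out / "features.csv",
        "metadata": out / "metadata.csv",
        "standards": out / "standards.csv",
        "truth_abundance": out / "truth_abundance.csv",
        "truth_rf": out / "truth_response_factors.csv",
        "truth_features": out / "truth_feature_species.csv",
    }
    write_mgf(bundle.spectra, paths["mgf"])
    write_feature_table(bundle.feature_table, paths["features"])
    bundle.metadata.to_csv(paths["metadata"], index=False)
    bundle.standards.to_csv(paths["standards"], index=False)
    bundle.truth.abundance.to_csv(paths["truth_abundance"], index_label="shorthand")
    pd.Series(bundle.truth.response_factors, name="rf").to_csv(paths["truth_rf"], index_label="key")
    pd.DataFrame(
        [(f, s, a) for f, (s, a) in bundle.truth.feature_species.items()],
        columns=["feature_id", "shorthand", "adduct"],
    ).to_csv(paths["truth_features"], index=False)
    return paths
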