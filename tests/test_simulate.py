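import filecmp

import numpy as np
import pandas as pd
import pytest

from sedlipidomics import chem
from sedlipidomics.simulate import (
    DEFAULT_SPHINGO_COUNTS,
    GeneratorConfig,
    generate_species_catalog,
    simulate_dataset,
    simulate_ms2,
    simulate_profiles,
    write_bundle,
)


def test_catalog_counts_match_config():
    cfg = GeneratorConfig(seed=3)
    catalog = generate_species_catalog(cfg)
    got = {}
    for sp in catalog:
        key = sp.subclass if sp.lipid_class == "sphingolipid" else sp.lipid_class
        got[key] = got.get(key, 0) + 1
    for sub, n in DEFAULT_SPHINGO_COUNTS.items():
        assert got[sub] == n
    for cls, n in cfg.other_counts.items():
        assert got[cls] == n


def test_sphingolipid_chain_bounds_and_odd_chains():
    catalog = generate_species_catalog(GeneratorConfig(seed=4))
    sph = [sp for sp in catalog if sp.lipid_class == "sphingolipid"]
    assert sph
    odd = 0
    for sp in sph:
        assert 15 <= sp.base_carbons <= 23
        assert 14 <= sp.fa_carbons <= 42
        if sp.subclass == "1-O-acylCer":
            assert 28 <= sp.extra_fa_carbons <= 32
        odd += sp.fa_carbons % 2
    assert odd > 0  # odd-carbon fatty acids occur (bacterial signature)
    even = sum(1 for sp in sph if sp.fa_carbons % 2 == 0)
    assert even > 0


def test_catalog_masses_formula_consistent():
    for sp in generate_species_catalog(GeneratorConfig(seed=5).small()):
        assert sp.mono_mass == pytest.approx(chem.monoisotopic_mass(sp.formula), abs=1e-4)


def test_single_subclass_config():
    cfg = GeneratorConfig(
        seed=1,
        sphingo_counts={"Cer": 5},
        other_counts={},
    )
    catalog = generate_species_catalog(cfg)
    assert len(catalog) == 5
    assert all(sp.subclass == "Cer" for sp in catalog)


def test_infeasible_chain_range_rejected():
    with pytest.raises(ValueError):
        generate_species_catalog(GeneratorConfig(base_carbon_range=(23, 15)))


# ---------------------------------------------------------------------------
# profiles


def test_noise_free_zone_fractions_hit_targets():
    cfg = GeneratorConfig(seed=6).noise_free()
    catalog = generate_species_catalog(cfg)
    abundance, _, _ = simulate_profiles(catalog, cfg)
    cls_of = {
        sp.shorthand: ("sphingolipid" if sp.lipid_class == "sphingolipid" else sp.lipid_class)
        for sp in catalog
    }
    by_class = abundance.groupby(abundance.index.map(cls_of)).sum()
    frac = by_class / by_class.sum(axis=0)
    for sid, matrix, depth, unit, zone, toc, vol in cfg.samples:
        for cls, target in cfg.zone_targets[zone].items():
            assert frac.loc[cls, sid] == pytest.approx(target, abs=1e-9), (sid, cls)


def test_default_sediment_sphingolipid_share_near_study_level():
    cfg = GeneratorConfig(seed=42)
    catalog = generate_species_catalog(cfg)
    abundance, _, _ = simulate_profiles(catalog, cfg)
    sph = [sp.shorthand for sp in catalog if sp.lipid_class == "sphingolipid"]
    sed = [s[0] for s in cfg.samples if s[1] == "sediment"]
    frac = abundance.loc[sph, sed].sum(axis=0) / abundance[sed].sum(axis=0)
    assert abs(frac.mean() - 0.21) < 0.03


def test_water_and_sediment_exclusive_sets_disjoint():
    cfg = GeneratorConfig(seed=7)
    catalog = generate_species_catalog(cfg)
    _, water_sph, sed_sph = simulate_profiles(catalog, cfg)
    water_only = water_sph - sed_sph
    sed_only = sed_sph - water_sph
    assert water_only.isdisjoint(sed_only)
    assert sed_only  # sediment-exclusive species exist


def test_unknown_zone_rejected():
    cfg = GeneratorConfig(samples=(("X", "water", 1, "mbsl", "oxic", None, 1.0),),
                          zone_targets={"euxinic": {"sterol": 1.0}})
    with pytest.raises(ValueError, match="zone"):
        simulate_profiles(generate_species_catalog(cfg.small()), cfg)


# ---------------------------------------------------------------------------
# spectra


def test_glycer_spectrum_contains_hexose_loss():
    cfg = GeneratorConfig(seed=8).noise_free()
    sp = chem.make_sphingolipid("Gly-Cer", 18, 1, 24, 0)
    spectrum = simulate_ms2(sp, cfg)
    target = spectrum.precursor_mz - chem.HEXOSE
    assert any(abs(p.mz - target) < 0.01 for p in spectrum.peaks)


def test_spectrum_deterministic_per_seed():
    cfg = GeneratorConfig(seed=9)
    sp = chem.make_sphingolipid("Cer", 18, 1, 24, 0)
    s1 = simulate_ms2(sp, cfg)
    s2 = simulate_ms2(sp, cfg)
    assert s1.precursor_mz == s2.precursor_mz
    np.testing.assert_array_equal(s1.mz, s2.mz)
    np.testing.assert_array_equal(s1.intensities, s2.intensities)


def test_homolog_precursor_spacing():
    cfg = GeneratorConfig(seed=10).noise_free()
    a = simulate_ms2(chem.make_sphingolipid("Cer", 18, 1, 24, 0), cfg)
    b = simulate_ms2(chem.make_sphingolipid("Cer", 18, 1, 25, 0), cfg)
    assert b.precursor_mz - a.precursor_mz == pytest.approx(chem.CH2, abs=1e-6)


def test_noise_free_spectra_have_enough_true_peaks(small_noise_free_bundle):
    for s in small_noise_free_bundle.spectra:
        assert len(s.peaks) >= 7  # the 6-matched-ion rule stays attainable


# ---------------------------------------------------------------------------
# full bundle


def test_noise_free_identity_rfs_areas_equal_truth():
    cfg = GeneratorConfig(seed=12, rf_log_sd=0.0).small().noise_free()
    b = simulate_dataset(cfg)
    # with rf distortion off (rf=100 for all), area = ng * 100
    for fid, (short, adduct) in b.truth.feature_species.items():
        sp = next(s for s in b.truth.catalog if s.shorthand == short)
        if sp.lipid_class == "sterol":
            continue  # adduct split applies
        for sid in b.truth.abundance.columns:
            assert b.feature_table.loc[fid, sid] == pytest.approx(
                100.0 * b.truth.abundance.loc[short, sid], rel=1e-12
            )


def test_same_seed_bundle_is_byte_identical(tmp_path):
    cfg = GeneratorConfig(seed=13).small()
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_bundle(simulate_dataset(cfg), d1)
    write_bundle(simulate_dataset(cfg), d2)
    for f in d1.iterdir():
        assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name


def test_truth_covers_every_feature(small_noise_free_bundle):
    b = small_noise_free_bundle
    from sedlipidomics.simulate import INTERNAL_STD_ID

    for fid in b.feature_table.index:
        if fid == INTERNAL_STD_ID:
            continue
        short, adduct = b.truth.feature_species[fid]
        assert short in b.truth.abundance.index
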