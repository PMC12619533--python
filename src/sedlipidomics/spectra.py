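"""MS² spectrum and feature-table I/O plus cross-sample feature alignment.

Spectra travel as MGF (the molecular-networking interchange format); feature
tables and sample metadata as delimited text (CSV/TSV autodetected by
extension). Retention times are minutes internally; MGF ``RTINSECONDS`` is
converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

#: duplicate fragment m/z within one spectrum are merged (intensity-summed)
#: at this tolerance (Da) to avoid double counting in cosine matching
MERGE_TOL = 0.002

WATER_ZONES = ("oxic", "suboxic", "euxinic")
SEDIMENT_ZONES = ("marine", "transitional", "lacustrine")

#: default sediment phase boundaries, cm below seafloor
SEDIMENT_PHASE_DEPTHS = {"marine": (5.0, 96.0), "transitional": (96.0, 136.0), "lacustrine": (136.0, 211.0)}


class MgfParseError(ValueError):
    """Malformed MGF block; carries the 1-based block index."""


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if not (np.isfinite(self.mz) and self.mz > 0):
            raise ValidationError(f"peak mz must be positive and finite, got {self.mz}")
        if not (np.isfinite(self.intensity) and self.intensity > 0):
            raise ValidationError(f"peak intensity must be positive and finite, got {self.intensity}")


@dataclass(frozen=True)
class Ms2Spectrum:
    """One precursor with its fragment peak list (sorted, de-duplicated)."""

    feature_id: str
    precursor_mz: float
    retention_time: float  # minutes
    peaks: tuple[Peak, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not (np.isfinite(self.precursor_mz) and self.precursor_mz > 0):
            raise ValidationError(f"precursor_mz must be positive, got {self.precursor_mz}")
        object.__setattr__(self, "peaks", _merge_peaks(self.peaks))

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


def _merge_peaks(peaks: Sequence[Peak], tol: float = MERGE_TOL) -> tuple[Peak, ...]:
    """Sort by m/z and merge duplicates within ``tol`` by intensity sum."""
    if not peaks:
        return ()
    ordered = sorted(peaks, key=lambda p: p.mz)
    merged: list[list[float]] = [[ordered[0].mz, ordered[0].intensity]]
    for p in ordered[1:]:
        if p.mz - merged[-1][0] <= tol:
            prev_mz, prev_int = merged[-1]
            tot = prev_int + p.intensity
            merged[-1] = [(prev_mz * prev_int + p.mz * p.intensity) / tot, tot]
        else:
            merged.append([p.mz, p.intensity])
    return tuple(Peak(mz, it) for mz, it in merged)


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read an MGF file into spectra; RT converted from seconds to minutes.

    Spectra with empty peak lists are skipped with a warning. A malformed
    block raises :class:`MgfParseError` naming the block index.
    """
    path = Path(path)
    spectra = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, entry in enumerate(reader, start=1):
                params = entry.get("params", {})
                try:
                    pepmass = params["pepmass"][0]
                    fid = str(
                        params.get("feature_id")
                        or params.get("title")
                        or f"spectrum_{i}"
                    )
                    rt = params.get("rtinseconds")
                    rt_min = float(rt) / 60.0 if rt is not None else 0.0
                    peaks = tuple(
                        Peak(float(m), float(s))
                        for m, s in zip(entry["m/z array"], entry["intensity array"])
                        if s > 0
                    )
                except (KeyError, TypeError, IndexError, ValueError) as exc:
                    raise MgfParseError(f"malformed MGF block {i} in {path}: {exc}") from exc
                if not peaks:
                    logger.warning("MGF block %d (%s): empty peak list, skipped", i, fid)
                    continue
                spectra.append(Ms2Spectrum(fid, float(pepmass), rt_min, peaks))
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF blocks in input order (lossless with read_mgf)."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE_ID={s.feature_id}\n")
            fh.write(f"TITLE={s.feature_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"RTINSECONDS={s.retention_time * 60.0:.4f}\n")
            fh.write("CHARGE=1+\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# feature tables and metadata

META_COLUMNS = ["sample_id", "matrix", "depth", "depth_unit", "zone", "toc_fraction", "filtered_volume"]
_FEATURE_COLS = ["mz", "rt"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate sample metadata (one row per sample)."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path))
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = set(["sample_id", "matrix", "zone"]) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns {sorted(missing)}")
    for _, row in meta.iterrows():
        m, z = row["matrix"], row["zone"]
        if m == "water" and z not in WATER_ZONES:
            raise ValidationError(f"sample {row['sample_id']}: zone {z!r} invalid for water")
        if m == "sediment" and z not in SEDIMENT_ZONES:
            raise ValidationError(f"sample {row['sample_id']}: zone {z!r} invalid for sediment")
        if m not in ("water", "sediment"):
            raise ValidationError(f"sample {row['sample_id']}: unknown matrix {m!r}")
        if m == "sediment":
            toc = row.get("toc_fraction")
            if not (toc is not None and 0 < float(toc) <= 1):
                raise ValidationError(f"sample {row['sample_id']}: toc_fraction must be in (0, 1]")
        if m == "water":
            vol = row.get("filtered_volume")
            if not (vol is not None and float(vol) > 0):
                raise ValidationError(f"sample {row['sample_id']}: filtered_volume must be > 0")
    return meta.reset_index(drop=True)


def read_feature_table(path: str | Path, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a feature table: index feature_id, columns mz, rt, then samples.

    Missing cells are gap-filled as 0. Negative areas and sample columns
    absent from the metadata are validation errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return validate_feature_table(df, metadata)


def validate_feature_table(df: pd.DataFrame, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _FEATURE_COLS and c != "spectrum_id"]
    if metadata is not None:
        known = set(metadata["sample_id"].astype(str))
        unknown = [c for c in sample_cols if c not in known]
        if unknown:
            raise ValidationError(f"sample columns not in metadata: {unknown}")
    areas = df[sample_cols].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    if (areas.to_numpy() < 0).any():
        bad = areas.lt(0).any()
        raise ValidationError(f"negative peak areas in columns {list(bad[bad].index)}")
    out = df.copy()
    out[sample_cols] = areas
    if out.index.duplicated().any():
        raise ValidationError("duplicate feature ids")
    out.index = out.index.astype(str)
    return out


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="feature_id")


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _FEATURE_COLS and c != "spectrum_id"]


# ---------------------------------------------------------------------------
# alignment


def align_features(
    per_sample_features: dict[str, Sequence[tuple[float, float, float]]],
    rt_tol_min: float = 0.5,
    mz_tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Greedy single-linkage alignment of per-sample (mz, rt, area) lists.

    Two features co-align iff |Δrt| ≤ ``rt_tol_min`` and |Δmz| within
    ``mz_tol_ppm``. Each linkage group becomes one row whose per-sample area
    is the sum of that sample's members; consensus m/z and RT are
    intensity-weighted means. Output is invariant to sample order.
    """
    if rt_tol_min <= 0 or mz_tol_ppm <= 0:
        raise ValueError("tolerances must be positive")
    records = []
    for sample in sorted(per_sample_features):
        for mz, rt, area in per_sample_features[sample]:
            records.append((float(mz), float(rt), float(area), sample))
    if not records:
        return pd.DataFrame(columns=_FEATURE_COLS)
    records.sort(key=lambda r: (r[0], r[1], r[3]))
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    mzs = np.array([r[0] for r in records])
    for i in range(n):
        tol_da = mzs[i] * mz_tol_ppm * 1e-6
        j = i + 1
        while j < n and mzs[j] - mzs[i] <= tol_da:
            if abs(records[j][1] - records[i][1]) <= rt_tol_min:
                union(i, j)
            j += 1

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    samples = sorted(per_sample_features)
    rows = []
    # deterministic row order: by consensus m/z then rt
    for members in groups.values():
        w = np.array([records[i][2] for i in members])
        w = np.where(w > 0, w, 1.0)
        cmz = float(np.average([records[i][0] for i in members], weights=w))
        crt = float(np.average([records[i][1] for i in members], weights=w))
        areas = {s: 0.0 for s in samples}
        for i in members:
            areas[records[i][3]] += records[i][2]
        rows.append((cmz, crt, areas, members))
    rows.sort(key=lambda r: (r[0], r[1]))
    data = {
        "mz": [r[0] for r in rows],
        "rt": [r[1] for r in rows],
    }
    for s in samples:
        data[s] = [r[2][s] for r in rows]
    index = [f"F{k + 1:05d}" for k in range(len(rows))]
    return pd.DataFrame(data, index=pd.Index(index, name="feature_id"))
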