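"""Spectra and feature handling for the seven-group co-culture design.

The experiment compares two axenic controls (G1 = axenic *A. unguis*, G2 =
axenic *A. terreus*) with five co-culture regimes (G3-G7) that differ in
inoculation order and inactivation.  Metabolite features detected in each
group are aligned into one table, fold-changes are computed against the
matching axenic reference, and peaks whose production changed substantially
(or appeared only in co-culture) are selected for dereplication.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem_mass import IsotopeEnvelope

__all__ = [
    "GROUPS",
    "GROUP_DESCRIPTIONS",
    "SCAN_RANGE_DA",
    "PDA_RANGE_NM",
    "END_ABSORPTION",
    "FragmentSpectrum",
    "ChromatographicFeature",
    "FeatureTable",
    "TrendCategory",
    "TrendRecord",
    "NewMetabolite",
    "read_mgf",
    "write_mgf",
    "read_feature_csv",
    "write_feature_csv",
    "align_features",
    "fold_change",
    "classify_trend",
    "select_differential",
    "trend_report",
]

logger = logging.getLogger(__name__)

#: The seven culture groups. G1/G2 are the axenic references.
GROUPS: tuple[str, ...] = ("G1", "G2", "G3", "G4", "G5", "G6", "G7")
GROUP_DESCRIPTIONS: Mapping[str, str] = {
    "G1": "axU (axenic A. unguis)",
    "G2": "axT (axenic A. terreus)",
    "G3": "iacU-livT (inactivated A. unguis then live A. terreus)",
    "G4": "livU-livT (live A. unguis then live A. terreus)",
    "G5": "livU/livT (simultaneous inoculation)",
    "G6": "iacT-livU (inactivated A. terreus then live A. unguis)",
    "G7": "livT-livU (live A. terreus then live A. unguis)",
}

#: Ion-trap acquisition bounds used as validation limits.
SCAN_RANGE_DA: tuple[float, float] = (100.0, 2000.0)
PDA_RANGE_NM: tuple[float, float] = (190.0, 600.0)

#: Sentinel for UV traces that rise only toward the solvent cutoff with no
#: distinct maximum ("end absorption").  Distinct from "no UV data".
END_ABSORPTION = "END_ABSORPTION"

KNOWN_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M-H]-", "unknown")


@dataclass(frozen=True)
class FragmentSpectrum:
    """One MS2 scan: precursor, polarity, retention time and fragment peaks."""

    spectrum_id: str
    precursor_mz: float
    polarity: str
    retention_time: float
    peaks: tuple[tuple[float, float], ...]
    group_id: str = ""

    def __post_init__(self) -> None:
        if not SCAN_RANGE_DA[0] <= self.precursor_mz <= SCAN_RANGE_DA[1]:
            raise ValueError(
                f"precursor m/z {self.precursor_mz} outside acquisition scan "
                f"range {SCAN_RANGE_DA}"
            )
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        pk = tuple(sorted(((float(m), float(i)) for m, i in self.peaks)))
        if any(i < 0 for _, i in pk):
            raise ValueError("fragment intensities must be >= 0")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))


@dataclass(frozen=True)
class ChromatographicFeature:
    """An integrated LC-MS feature from one culture group."""

    mz: float
    retention_time: float
    adduct: str = "unknown"
    area: float = 0.0
    uv_maxima: tuple[float, ...] | str | None = None
    isotope_cluster: IsotopeEnvelope | None = None
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("feature area must be >= 0")
        if self.adduct not in KNOWN_ADDUCTS:
            raise ValueError(f"unknown adduct {self.adduct!r}; expected one of {KNOWN_ADDUCTS}")
        uv = self.uv_maxima
        if uv is not None and uv != END_ABSORPTION:
            uv = tuple(float(x) for x in uv)
            if any(not PDA_RANGE_NM[0] <= x <= PDA_RANGE_NM[1] for x in uv):
                raise ValueError(f"UV maxima {uv} outside PDA range {PDA_RANGE_NM}")
            object.__setattr__(self, "uv_maxima", uv)


class TrendCategory(str, Enum):
    DECREASED_5X_OR_MORE = "decreased_5x_or_more"
    DECREASED_LT_5X = "decreased_lt_5x"
    UNCHANGED = "unchanged"
    INCREASED_LT_5X = "increased_lt_5x"
    INCREASED_5X_OR_MORE = "increased_5x_or_more"
    NEW_MINOR = "new_minor"
    NEW_MAJOR = "new_major"


@dataclass(frozen=True)
class NewMetabolite:
    """Fold-change marker: absent in the reference, detected in the test."""

    area: float


@dataclass(frozen=True)
class TrendRecord:
    peak_id: str
    group: str
    fold: float | NewMetabolite | None
    category: TrendCategory | None


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path, group_id: str = "") -> list[FragmentSpectrum]:
    """Read an MGF file into :class:`FragmentSpectrum` records.

    Polarity is inferred from the CHARGE sign; RTINSECONDS is converted to
    minutes.  Blocks without PEPMASS are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[FragmentSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("%s: block %d missing PEPMASS, skipped", path, idx)
                continue
            charges = params.get("charge")
            polarity = "positive"
            if charges is not None and len(charges) and int(charges[0]) < 0:
                polarity = "negative"
            rt_s = params.get("rtinseconds", 0.0)
            peaks = tuple(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(
                FragmentSpectrum(
                    spectrum_id=str(params.get("title", f"{path.stem}:{idx}")),
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    retention_time=float(rt_s) / 60.0,
                    peaks=peaks,
                    group_id=group_id or str(params.get("group", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str | Path) -> None:
    """Write spectra to MGF; inverse of :func:`read_mgf`."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": (s.precursor_mz,),
                    "rtinseconds": s.retention_time * 60.0,
                    "charge": "1+" if s.polarity == "positive" else "1-",
                    "group": s.group_id,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Feature CSV I/O
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["mz", "rt", "adduct", "area", "uv_maxima", "isotope_mz", "isotope_intensity", "group"]


def _uv_to_str(uv) -> str:
    if uv is None:
        return ""
    if uv == END_ABSORPTION:
        return END_ABSORPTION
    return ";".join(f"{x:g}" for x in uv)


def _uv_from_str(text: str):
    if not text or text != text:  # '' or NaN
        return None
    if text == END_ABSORPTION:
        return END_ABSORPTION
    return tuple(float(x) for x in str(text).split(";"))


def write_feature_csv(features: Sequence[ChromatographicFeature], path: str | Path) -> None:
    rows = []
    for f in features:
        iso_mz = iso_int = ""
        if f.isotope_cluster is not None:
            iso_mz = ";".join(f"{m:.5f}" for m in f.isotope_cluster.masses)
            iso_int = ";".join(f"{i:.6f}" for i in f.isotope_cluster.intensities)
        rows.append(
            [f.mz, f.retention_time, f.adduct, f.area, _uv_to_str(f.uv_maxima), iso_mz, iso_int, f.group_id]
        )
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_csv(path: str | Path, group_id: str = "") -> list[ChromatographicFeature]:
    df = pd.read_csv(path, keep_default_na=False)
    feats = []
    for _, row in df.iterrows():
        cluster = None
        if str(row.get("isotope_mz", "")):
            masses = [float(x) for x in str(row["isotope_mz"]).split(";")]
            intens = [float(x) for x in str(row["isotope_intensity"]).split(";")]
            cluster = IsotopeEnvelope(peaks=tuple(zip(masses, intens)))
        feats.append(
            ChromatographicFeature(
                mz=float(row["mz"]),
                retention_time=float(row["rt"]),
                adduct=str(row["adduct"]) if str(row["adduct"]) else "unknown",
                area=float(row["area"]),
                uv_maxima=_uv_from_str(str(row.get("uv_maxima", ""))),
                isotope_cluster=cluster,
                group_id=group_id or str(row.get("group", "")),
            )
        )
    return feats


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class _Row:
    mz: float
    rt: float
    adduct: str
    areas: dict[str, float]
    uv_maxima: tuple[float, ...] | str | None = None
    isotope_cluster: IsotopeEnvelope | None = None

    def weight(self) -> float:
        return sum(self.areas.values()) or 1.0


class FeatureTable:
    """Aligned features x culture groups with per-group integrated areas."""

    def __init__(self, rows: Mapping[str, _Row], groups: Sequence[str] = GROUPS):
        self.groups = tuple(groups)
        self._rows = dict(rows)

    @property
    def peak_ids(self) -> list[str]:
        return list(self._rows)

    def row(self, peak_id: str) -> _Row:
        return self._rows[peak_id]

    def area(self, peak_id: str, group: str) -> float:
        if group not in self.groups:
            raise KeyError(f"unknown group label {group!r}")
        return self._rows[peak_id].areas.get(group, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for pid, row in self._rows.items():
            rec = {"peak_id": pid, "mz": row.mz, "rt": row.rt, "adduct": row.adduct}
            for g in self.groups:
                rec[f"area_{g}"] = row.areas.get(g, 0.0)
            records.append(rec)
        return pd.DataFrame(records)

    @classmethod
    def from_areas(
        cls,
        areas: Mapping[str, Mapping[str, float]],
        groups: Sequence[str] = GROUPS,
        mz: Mapping[str, float] | None = None,
        rt: Mapping[str, float] | None = None,
    ) -> "FeatureTable":
        """Build a table directly from {peak_id: {group: area}} maps."""
        rows = {}
        for pid, by_group in areas.items():
            rows[pid] = _Row(
                mz=(mz or {}).get(pid, 0.0) or 0.0,
                rt=(rt or {}).get(pid, 0.0) or 0.0,
                adduct="unknown",
                areas={g: float(a) for g, a in by_group.items()},
            )
        return cls(rows, groups)

    def __len__(self) -> int:
        return len(self._rows)


def align_features(
    groups: Mapping[str, Sequence[ChromatographicFeature]],
    mz_tol: float = 0.3,
    rt_tol: float = 0.5,
    group_scale: Mapping[str, float] | None = None,
) -> FeatureTable:
    """Greedy nearest-neighbour alignment of per-group feature lists.

    A feature joins an existing consensus row iff both |d(mz)| <= mz_tol and
    |d(rt)| <= rt_tol against the row consensus (area-weighted means);
    ties break by smallest |d(mz)| then smallest |d(rt)|.  Unmatched
    features open singleton rows with zero areas elsewhere.  ``group_scale``
    optionally rescales each group's areas (total-extract proportionality);
    factor 1 when unknown.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("alignment tolerances must be > 0")
    scale = dict(group_scale or {})
    rows: list[_Row] = []
    for group in sorted(groups):
        factor = scale.get(group, 1.0)
        # deterministic order: largest areas first so consensus anchors on
        # the strongest signals
        feats = sorted(groups[group], key=lambda f: (-f.area, f.mz, f.retention_time))
        for f in feats:
            best = None
            for row in rows:
                d_mz = abs(f.mz - row.mz)
                d_rt = abs(f.retention_time - row.rt)
                if d_mz <= mz_tol and d_rt <= rt_tol and group not in row.areas:
                    key = (d_mz, d_rt)
                    if best is None or key < best[0]:
                        best = (key, row)
            area = f.area * factor
            if best is None:
                rows.append(
                    _Row(
                        mz=f.mz,
                        rt=f.retention_time,
                        adduct=f.adduct,
                        areas={group: area},
                        uv_maxima=f.uv_maxima,
                        isotope_cluster=f.isotope_cluster,
                    )
                )
            else:
                row = best[1]
                w_old = row.weight()
                w_new = area or 1.0
                total = w_old + w_new
                row.mz = (row.mz * w_old + f.mz * w_new) / total
                row.rt = (row.rt * w_old + f.retention_time * w_new) / total
                row.areas[group] = row.areas.get(group, 0.0) + area
                if row.uv_maxima is None:
                    row.uv_maxima = f.uv_maxima
                if row.isotope_cluster is None:
                    row.isotope_cluster = f.isotope_cluster
                if row.adduct == "unknown":
                    row.adduct = f.adduct
    rows.sort(key=lambda r: (r.rt, r.mz))
    return FeatureTable({f"P{i + 1}": row for i, row in enumerate(rows)}, tuple(sorted(groups)))


# ---------------------------------------------------------------------------
# Fold change and trend classification
# ---------------------------------------------------------------------------

def default_detect_floor(areas: Sequence[float]) -> float:
    """Blank-free detection floor: 3x the median of the bottom decile."""
    nonzero = sorted(a for a in areas if a > 0)
    if not nonzero:
        return 0.0
    decile = nonzero[: max(1, len(nonzero) // 10)]
    return 3.0 * float(np.median(decile))


def fold_change(
    table: FeatureTable,
    peak_id: str,
    test_group: str,
    reference_group: str,
    detect_floor: float = 0.0,
) -> float | NewMetabolite | None:
    """Test/reference area ratio, or NEW if absent in the reference.

    Returns the ratio rounded to 2 decimals when the reference is detected,
    a :class:`NewMetabolite` carrying the test area when only the test is,
    and None when neither is above ``detect_floor``.
    """
    if detect_floor < 0:
        raise ValueError("detect_floor must be >= 0")
    test = table.area(peak_id, test_group)
    ref = table.area(peak_id, reference_group)
    if ref > detect_floor:
        return round(test / ref, 2)
    if test > detect_floor:
        return NewMetabolite(area=test)
    return None


def classify_trend(
    fold_or_new: float | NewMetabolite,
    new_abundance_threshold: float = float("inf"),
) -> TrendCategory:
    """Map a fold value (or NEW marker) onto the trend legend.

    "Fivefold and more" is inclusive: fold <= 0.2 and fold >= 5 fall into
    the strong categories.  Fold 0 (metabolite eliminated) counts as a
    fivefold-or-more decrease.  NEW metabolites split into major/minor at
    ``new_abundance_threshold``.
    """
    if isinstance(fold_or_new, NewMetabolite):
        if fold_or_new.area >= new_abundance_threshold:
            return TrendCategory.NEW_MAJOR
        return TrendCategory.NEW_MINOR
    fold = float(fold_or_new)
    if fold < 0:
        raise ValueError("fold change cannot be negative")
    if fold <= 0.2:
        return TrendCategory.DECREASED_5X_OR_MORE
    if fold < 1:
        return TrendCategory.DECREASED_LT_5X
    if fold == 1:
        return TrendCategory.UNCHANGED
    if fold < 5:
        return TrendCategory.INCREASED_LT_5X
    return TrendCategory.INCREASED_5X_OR_MORE


def _reference_pairs(
    reference_map: Mapping[str, str | Sequence[str]],
) -> list[tuple[str, str]]:
    """Normalise {group: ref | [refs]} into (group, ref) pairs.

    A co-culture group may be compared against both axenic references when a
    peak is produced by both strains.
    """
    pairs: list[tuple[str, str]] = []
    for group, refs in reference_map.items():
        if isinstance(refs, str):
            refs = [refs]
        for ref in refs:
            pairs.append((group, ref))
    return pairs


def select_differential(
    table: FeatureTable,
    reference_map: Mapping[str, str | Sequence[str]],
    min_fold: float = 2.0,
    detect_floor: float = 0.0,
) -> list[str]:
    """Select peaks whose yield varies substantially in any co-culture group.

    ``reference_map`` maps each co-culture group to its axenic reference; a
    peak qualifies when, under at least one reference, at least one group
    shows a NEW marker, a fold >= min_fold, or a fold <= 1/min_fold.  A peak
    attributable to both references is counted once.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    pairs = _reference_pairs(reference_map)
    missing = sorted({ref for _, ref in pairs} - set(table.groups))
    if missing:
        raise KeyError(f"reference group(s) {missing} absent from the table")
    selected = []
    for pid in table.peak_ids:
        hit = False
        for group, ref in pairs:
            fc = fold_change(table, pid, group, ref, detect_floor)
            if fc is None:
                continue
            if isinstance(fc, NewMetabolite) or fc >= min_fold or fc <= 1.0 / min_fold:
                hit = True
                break
        if hit:
            selected.append(pid)
    return selected


def trend_report(
    table: FeatureTable,
    reference_map: Mapping[str, str | Sequence[str]],
    detect_floor: float = 0.0,
    new_abundance_threshold: float | None = None,
) -> pd.DataFrame:
    """Long-format fold/trend report: one row per (peak, co-culture group)."""
    if new_abundance_threshold is None:
        all_areas = [
            table.area(pid, g) for pid in table.peak_ids for g in table.groups
        ]
        nonzero = [a for a in all_areas if a > 0]
        new_abundance_threshold = float(np.median(nonzero)) if nonzero else float("inf")
    records = []
    pairs = _reference_pairs(reference_map)
    for pid in table.peak_ids:
        row = table.row(pid)
        for group, ref in pairs:
            fc = fold_change(table, pid, group, ref, detect_floor)
            cat = classify_trend(fc, new_abundance_threshold) if fc is not None else None
            records.append(
                {
                    "peak_id": pid,
                    "mz": row.mz,
                    "rt": row.rt,
                    "adduct": row.adduct,
                    "group": group,
                    "reference": ref,
                    "area": table.area(pid, group),
                    "fold": fc.area if isinstance(fc, NewMetabolite) else fc,
                    "is_new": isinstance(fc, NewMetabolite),
                    "category": cat.value if cat else "",
                }
            )
    return pd.DataFrame(records)
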