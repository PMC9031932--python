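"""Candidate-catalog dereplication of differential peaks.

Annotation follows the multi-criteria mining strategy used for fungal
co-culture extracts: deduce the neutral mass from the observed adduct,
window the catalog at +/- 1 Da (+/- 2 Da for chlorinated species, whose
average masses shift with the isotope cluster), check UV compatibility,
scope candidates by taxonomy (genus first, the fungal kingdom as a
fallback), verify chlorine counts against the observed isotope envelope,
and star hits supported by at least one line of evidence beyond the
molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_mass import (
    HalogenCall,
    IsotopeEnvelope,
    MolecularFormula,
    average_mass,
    classify_halogenation,
    parse_formula,
    regularize_envelope,
)
from .spectra_features import END_ABSORPTION, ChromatographicFeature

__all__ = [
    "PROTON_MASS",
    "SODIUM_ION_MASS",
    "ADDUCT_SHIFTS",
    "UVVerdict",
    "CandidateRecord",
    "AnnotationEvidence",
    "AnnotationHit",
    "deduce_neutral_mass",
    "mw_filter",
    "uv_compatibility",
    "taxon_scope",
    "flag_reliability",
    "annotate_peak",
    "halogenation_by_taxon",
    "read_catalog",
    "write_catalog",
    "annotation_report",
]

PROTON_MASS = 1.00728
SODIUM_ION_MASS = 22.98922

#: m/z = neutral mass + shift for each supported adduct.
ADDUCT_SHIFTS: Mapping[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": SODIUM_ION_MASS,
    "[M-H]-": -PROTON_MASS,
}


class UVVerdict(str, Enum):
    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CandidateRecord:
    """One natural-product catalog entry (local stand-in for DB records)."""

    name: str
    mw: float = 0.0
    formula: MolecularFormula | None = None
    uv_maxima: tuple[float, ...] | str | None = None
    taxon: str = ""
    fungal: bool = True
    source_db: str = ""
    record_id: str = ""
    activity: str = ""
    doi: str = ""
    ms2_cosine: float | None = None

    def __post_init__(self) -> None:
        mw = self.mw
        if self.formula is not None:
            computed = average_mass(self.formula)
            if mw:
                if abs(mw - computed) > 0.05:
                    raise ValueError(
                        f"{self.name}: catalog MW {mw} disagrees with formula "
                        f"{self.formula} (average mass {computed:.2f})"
                    )
            else:
                mw = round(computed, 2)
                object.__setattr__(self, "mw", mw)
        if mw <= 0:
            raise ValueError(f"{self.name}: candidate must carry a positive MW or a formula")

    @property
    def n_cl(self) -> int:
        return self.formula["Cl"] if self.formula is not None else 0


@dataclass(frozen=True)
class AnnotationEvidence:
    mw_match: bool
    ms2_cosine: float | None = None
    uv: UVVerdict = UVVerdict.UNKNOWN
    isotope_consistent: bool = False
    taxon_in_genus: bool = False

    @property
    def positive_flags(self) -> list[str]:
        flags = []
        if self.ms2_cosine is not None:
            flags.append(f"ms2_cosine={self.ms2_cosine:.2f}")
        if self.uv is UVVerdict.COMPATIBLE:
            flags.append("uv_compatible")
        if self.isotope_consistent:
            flags.append("isotope_consistent")
        if self.taxon_in_genus:
            flags.append("taxon_in_genus")
        return flags


@dataclass(frozen=True)
class AnnotationHit:
    peak_id: str
    candidate: CandidateRecord
    evidence: AnnotationEvidence
    starred: bool
    excluded: bool = False
    delta_mw: float = 0.0
    stage: int = 1


def deduce_neutral_mass(mz: float, adduct: str) -> float:
    """Neutral mass from a measured m/z and its adduct assignment."""
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCT_SHIFTS)}")
    return round(mz - ADDUCT_SHIFTS[adduct], 2)


def mw_filter(
    catalog: Sequence[CandidateRecord],
    neutral_mass: float,
    chlorinated: bool = False,
) -> list[CandidateRecord]:
    """Catalog entries within the MW window, nearest first.

    Window is +/- 1 Da, widened to +/- 2 Da for chlorinated peaks (the
    average mass of a polychlorinated species sits well above the
    monoisotopic ion actually measured).
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    window = 2.0 if chlorinated else 1.0
    hits = [c for c in catalog if abs(c.mw - neutral_mass) <= window]
    hits.sort(key=lambda c: (abs(c.mw - neutral_mass), c.name))
    return hits


def uv_compatibility(
    measured: Sequence[float] | str | None,
    candidate: Sequence[float] | str | None,
    tol: float = 15.0,
) -> UVVerdict:
    """Judge whether a candidate's literature UV maxima fit the measured ones.

    Returns UNKNOWN when either side has no recorded UV data.  A measured
    end-absorption-only trace is incompatible with any candidate showing a
    genuine maximum above 250 nm (and vice versa).  Otherwise the two peak
    lists are matched within ``tol`` nm in both directions and the mean of
    the two matched fractions must reach 1/2 for compatibility — a
    symmetric criterion, so a candidate with one lucky coincident maximum
    among many measured bands does not pass.
    """
    if tol <= 0:
        raise ValueError("UV tolerance must be > 0")
    if candidate is None or measured is None:
        return UVVerdict.UNKNOWN
    meas_end = measured == END_ABSORPTION
    cand_end = candidate == END_ABSORPTION
    if meas_end or cand_end:
        if meas_end and cand_end:
            return UVVerdict.COMPATIBLE
        other = candidate if meas_end else measured
        if any(x > 250.0 for x in other):
            return UVVerdict.INCOMPATIBLE
        return UVVerdict.COMPATIBLE
    meas = [float(x) for x in measured]
    cand = [float(x) for x in candidate]
    if not meas or not cand:
        return UVVerdict.UNKNOWN

    def matched_fraction(src: list[float], dst: list[float]) -> float:
        return sum(1 for x in src if any(abs(x - y) <= tol for y in dst)) / len(src)

    score = 0.5 * (matched_fraction(cand, meas) + matched_fraction(meas, cand))
    return UVVerdict.COMPATIBLE if score >= 0.5 else UVVerdict.INCOMPATIBLE


def _in_genus(taxon: str, genus: str) -> bool:
    taxon = taxon.strip()
    if not taxon:
        return False
    head = taxon.split()[0]
    abbrev = f"{genus[0].upper()}."
    # abbreviated binomials ("A. terreus", sometimes typeset "A.terreus")
    return head.lower() == genus.lower() or head == abbrev or head.startswith(abbrev)


def taxon_scope(
    catalog: Sequence[CandidateRecord], genus: str
) -> tuple[list[CandidateRecord], list[CandidateRecord]]:
    """Two-stage taxonomic scoping: (genus members, all fungal records).

    Stage 1 restricts to the producing genus; stage 2 (consulted when stage
    1 yields nothing reliable) widens to the fungal kingdom.
    """
    if not genus:
        raise ValueError("genus must be non-empty")
    stage1 = [c for c in catalog if _in_genus(c.taxon, genus)]
    stage2 = [c for c in catalog if c.fungal]
    return stage1, stage2


def flag_reliability(evidence: AnnotationEvidence) -> tuple[bool, bool]:
    """Return (starred, excluded) for a candidate's evidence.

    A hit is starred when the MW matches AND at least one further line of
    evidence supports it: an MS2 library match, compatible UV, a consistent
    chlorine isotope count, or genus-level taxonomy.  A UV-incompatible hit
    is excluded — unless an MS2 match exists, which is taken as stronger
    evidence than literature UV values recorded in different solvents.
    """
    excluded = evidence.uv is UVVerdict.INCOMPATIBLE and evidence.ms2_cosine is None
    starred = (
        not excluded
        and evidence.mw_match
        and (
            evidence.ms2_cosine is not None
            or evidence.uv is UVVerdict.COMPATIBLE
            or evidence.isotope_consistent
            or evidence.taxon_in_genus
        )
    )
    return starred, excluded


def annotate_peak(
    peak_id: str,
    mz: float,
    adduct: str,
    catalog: Sequence[CandidateRecord],
    genus: str = "Aspergillus",
    uv_measured: Sequence[float] | str | None = None,
    isotope_cluster: IsotopeEnvelope | None = None,
    ms2_cosines: Mapping[str, float] | None = None,
    uv_tol: float = 15.0,
    n_cl_max: int = 4,
) -> list[AnnotationHit]:
    """Full multi-criteria annotation of one differential peak.

    The observed isotope cluster (if any) is classified into a chlorine
    count first; a non-zero call widens the MW window and adds
    isotope-consistency evidence for candidates with the same Cl count.
    MS2 evidence comes from ``ms2_cosines`` (candidate name -> cosine) or,
    failing that, from a cosine stored on the catalog record.
    """
    halogen_call: HalogenCall | None = None
    if isotope_cluster is not None and len(isotope_cluster.peaks) >= 1:
        trimmed = regularize_envelope(isotope_cluster)
        if len(trimmed.peaks) >= 2:
            halogen_call = classify_halogenation(trimmed, n_max=n_cl_max)
    n_cl_obs = halogen_call.n_cl if halogen_call else 0
    chlorinated = n_cl_obs > 0
    neutral = deduce_neutral_mass(mz, adduct)

    stage1, stage2 = taxon_scope(catalog, genus)

    def build_hits(pool: Sequence[CandidateRecord], stage: int) -> list[AnnotationHit]:
        hits = []
        for cand in mw_filter(pool, neutral, chlorinated):
            cosine = None
            if ms2_cosines and cand.name in ms2_cosines:
                cosine = ms2_cosines[cand.name]
            elif cand.ms2_cosine is not None:
                cosine = cand.ms2_cosine
            evidence = AnnotationEvidence(
                mw_match=True,
                ms2_cosine=cosine,
                uv=uv_compatibility(uv_measured, cand.uv_maxima, uv_tol),
                isotope_consistent=chlorinated and cand.n_cl == n_cl_obs,
                taxon_in_genus=_in_genus(cand.taxon, genus),
            )
            starred, excluded = flag_reliability(evidence)
            hits.append(
                AnnotationHit(
                    peak_id=peak_id,
                    candidate=cand,
                    evidence=evidence,
                    starred=starred,
                    excluded=excluded,
                    delta_mw=round(cand.mw - neutral, 2),
                    stage=stage,
                )
            )
        return hits

    hits = build_hits(stage1, stage=1)
    if not any(h.starred for h in hits):
        seen = {h.candidate.name for h in hits}
        hits += [h for h in build_hits(stage2, stage=2) if h.candidate.name not in seen]
    return hits


def halogenation_by_taxon(
    record_counts: Sequence[int],
    chlorinated_counts: Sequence[int],
) -> float:
    """Percentage of chlorinated records across per-source record counts.

    Sources are counted independently (duplicate records across databases
    are deliberately not collapsed); the result is rounded to one decimal.
    """
    total = sum(record_counts)
    chlorinated = sum(chlorinated_counts)
    if total <= 0:
        raise ValueError("total record count must be positive")
    return round(100.0 * chlorinated / total, 1)


# ---------------------------------------------------------------------------
# Catalog CSV I/O
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "name", "formula", "mw", "uv_maxima", "taxon", "fungal",
    "source_db", "record_id", "activity", "doi", "ms2_cosine",
]


def _uv_to_str(uv) -> str:
    if uv is None:
        return ""
    if uv == END_ABSORPTION:
        return END_ABSORPTION
    return ";".join(f"{x:g}" for x in uv)


def _uv_from_str(text: str):
    text = str(text).strip()
    if not text:
        return None
    if text == END_ABSORPTION:
        return END_ABSORPTION
    return tuple(float(x) for x in text.split(";"))


def write_catalog(catalog: Sequence[CandidateRecord], path: str | Path) -> None:
    rows = []
    for c in catalog:
        rows.append(
            [
                c.name,
                str(c.formula) if c.formula is not None else "",
                c.mw,
                _uv_to_str(c.uv_maxima),
                c.taxon,
                c.fungal,
                c.source_db,
                c.record_id,
                c.activity,
                c.doi,
                "" if c.ms2_cosine is None else c.ms2_cosine,
            ]
        )
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, index=False)


def read_catalog(path: str | Path) -> list[CandidateRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"candidate catalog not found: {path}")
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        formula_text = str(row.get("formula", "")).strip()
        ms2 = str(row.get("ms2_cosine", "")).strip()
        records.append(
            CandidateRecord(
                name=str(row["name"]),
                formula=parse_formula(formula_text) if formula_text else None,
                mw=float(row["mw"]) if str(row.get("mw", "")).strip() else 0.0,
                uv_maxima=_uv_from_str(row.get("uv_maxima", "")),
                taxon=str(row.get("taxon", "")),
                fungal=str(row.get("fungal", "True")).strip().lower() in ("true", "1", "yes"),
                source_db=str(row.get("source_db", "")),
                record_id=str(row.get("record_id", "")),
                activity=str(row.get("activity", "")),
                doi=str(row.get("doi", "")),
                ms2_cosine=float(ms2) if ms2 else None,
            )
        )
    return records


def annotation_report(hits: Iterable[AnnotationHit]) -> pd.DataFrame:
    """Flat annotation table: one row per (peak, candidate) hit."""
    records = []
    for h in hits:
        records.append(
            {
                "peak_id": h.peak_id,
                "candidate": h.candidate.name,
                "library_mw": h.candidate.mw,
                "delta_mw": h.delta_mw,
                "formula": str(h.candidate.formula) if h.candidate.formula else "",
                "source_db": h.candidate.source_db,
                "record_id": h.candidate.record_id,
                "taxon": h.candidate.taxon,
                "stage": h.stage,
                "ms2_cosine": h.evidence.ms2_cosine,
                "uv": h.evidence.uv.value,
                "isotope_consistent": h.evidence.isotope_consistent,
                "taxon_in_genus": h.evidence.taxon_in_genus,
                "starred": h.starred,
                "excluded": h.excluded,
            }
        )
    return pd.DataFrame(records)
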