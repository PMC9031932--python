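"""Bundled worked-example data: a published two-strain co-culture screen.

Three small fixtures transcribed from a published *Aspergillus terreus* /
*A. unguis* co-culture study ship with the package:

* ``demo_fold_matrix`` — the fold-change matrix of the 15 differential
  peaks across the five co-culture groups, against their axenic references;
* ``demo_catalog`` — the natural-product candidate records (name, formula,
  library MW, literature UV maxima, taxon, source DB, library MS/MS cosine
  where one existed) that the study's database mining surfaced;
* ``demo_peaks`` — the measured evidence per peak (m/z, adduct, retention
  time, UV maxima, chlorine isotope clusters).

Together they form a complete worked example for the dereplication stage
without any network access.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .chem_mass import IsotopeEnvelope
from .dereplication import AnnotationHit, CandidateRecord, annotate_peak, read_catalog
from .spectra_features import END_ABSORPTION, FeatureTable

__all__ = [
    "DemoPeak",
    "load_demo_fold_matrix",
    "load_demo_catalog",
    "load_demo_peaks",
    "demo_feature_table",
    "annotate_demo_peak",
]


def _data_path(name: str):
    return resources.files("mycoderep.data").joinpath(name)


def load_demo_fold_matrix() -> pd.DataFrame:
    """Tidy fold matrix: (reference, peak, group, fold, is_new, new_major).

    Censored "<0.01" entries are parsed as 0.005 (any value at or below the
    fivefold boundary classifies identically); "NEW:<amount>:<major|minor>"
    marks metabolites absent from the axenic reference.
    """
    with _data_path("demo_fold_matrix.csv").open() as fh:
        wide = pd.read_csv(fh, dtype=str)
    records = []
    for _, row in wide.iterrows():
        for group in ("G3", "G4", "G5", "G6", "G7"):
            cell = str(row[group]).strip()
            is_new = cell.startswith("NEW:")
            new_major = None
            if is_new:
                _, amount, size = cell.split(":")
                fold = float(amount)
                new_major = size == "major"
            elif cell.startswith("<"):
                fold = float(cell[1:]) / 2.0
            else:
                fold = float(cell)
            records.append(
                {
                    "reference": row["reference"],
                    "peak": int(row["peak"]),
                    "group": group,
                    "fold": fold,
                    "is_new": is_new,
                    "new_major": new_major,
                }
            )
    return pd.DataFrame(records)


def demo_feature_table(base_area: float = 100.0) -> FeatureTable:
    """Reconstruct a feature area table realising the demo fold matrix.

    Each peak's axenic reference gets ``base_area``; co-culture areas are
    ``base_area x fold``.  The peak produced by both strains appears as one
    row whose two reference areas are set in the (constant) ratio its two
    fold blocks imply, so both blocks are reproduced from a single feature.
    NEW peaks have zero in both references.
    """
    tidy = load_demo_fold_matrix()
    areas: dict[str, dict[str, float]] = {}
    for (peak,), block in tidy.groupby(["peak"]):
        pid = str(peak)
        by_group: dict[str, float] = {g: 0.0 for g in ("G1", "G2", "G3", "G4", "G5", "G6", "G7")}
        refs = sorted(block["reference"].unique())
        if any(block["is_new"]):
            # absent from the axenic reference; NEW amounts are relative
            for _, row in block.iterrows():
                if row["is_new"]:
                    by_group[row["group"]] = base_area * row["fold"]
        elif len(refs) == 2:
            # shared metabolite: anchor areas on the G1 block, choose the G2
            # reference area from the (empirically constant) fold ratio
            g1_block = block[block["reference"] == "G1"]
            g2_block = block[block["reference"] == "G2"]
            by_group["G1"] = base_area
            ratio = (
                g1_block["fold"].to_numpy() / g2_block["fold"].to_numpy()
            ).mean()
            by_group["G2"] = base_area * ratio
            for _, row in g1_block.iterrows():
                by_group[row["group"]] = base_area * row["fold"]
        else:
            ref = refs[0]
            by_group[ref] = base_area
            for _, row in block.iterrows():
                by_group[row["group"]] = base_area * row["fold"]
        areas[pid] = by_group
    return FeatureTable.from_areas(areas)


def load_demo_catalog() -> list[CandidateRecord]:
    """The bundled natural-product candidate catalog."""
    with resources.as_file(_data_path("demo_catalog.csv")) as path:
        return read_catalog(path)


@dataclass(frozen=True)
class DemoPeak:
    peak_id: str
    mz: float
    adduct: str
    polarity: str
    rt: float
    uv_maxima: tuple[float, ...] | str | None
    isotope_cluster: IsotopeEnvelope | None


def load_demo_peaks() -> dict[str, DemoPeak]:
    """Measured evidence for the 15 differential peaks, keyed by peak id."""
    with _data_path("demo_peaks.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    peaks = {}
    for _, row in df.iterrows():
        uv_text = str(row["uv_maxima"]).strip()
        if not uv_text:
            uv = None
        elif uv_text == END_ABSORPTION:
            uv = END_ABSORPTION
        else:
            uv = tuple(float(x) for x in uv_text.split(";"))
        cluster = None
        if str(row["isotope_mz"]).strip():
            masses = [float(x) for x in row["isotope_mz"].split(";")]
            intens = [float(x) for x in row["isotope_intensity"].split(";")]
            cluster = IsotopeEnvelope(peaks=tuple(zip(masses, intens)))
        pid = str(row["peak"])
        peaks[pid] = DemoPeak(
            peak_id=pid,
            mz=float(row["mz"]),
            adduct=str(row["adduct"]),
            polarity=str(row["polarity"]),
            rt=float(row["rt"]),
            uv_maxima=uv,
            isotope_cluster=cluster,
        )
    return peaks


def annotate_demo_peak(peak_id: str, **kwargs) -> list[AnnotationHit]:
    """Run the full multi-criteria annotation for one bundled demo peak."""
    peak = load_demo_peaks()[peak_id]
    return annotate_peak(
        peak_id=peak.peak_id,
        mz=peak.mz,
        adduct=peak.adduct,
        catalog=load_demo_catalog(),
        uv_measured=peak.uv_maxima,
        isotope_cluster=peak.isotope_cluster,
        **kwargs,
    )
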