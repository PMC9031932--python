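"""End-to-end orchestration: features -> trends -> networks -> annotation.

This is the programmatic core behind the command-line interface: it
validates a :class:`PipelineConfig`, reads the per-group inputs, and writes
the four report artifacts (fold/trend matrix, annotation report, GraphML
networks per polarity, run log).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Mapping, Sequence

import networkx
import numpy
import pandas as pd
import pydantic
import scipy
from pydantic import BaseModel, Field

from . import __version__
from .dereplication import annotate_peak, annotation_report, read_catalog
from .molecular_network import build_network, split_nodes_by_rt, write_graphml
from .spectra_features import (
    GROUPS,
    FeatureTable,
    NewMetabolite,
    align_features,
    classify_trend,
    fold_change,
    read_feature_csv,
    read_mgf,
)

__all__ = [
    "PipelineConfig",
    "attribute_references",
    "differential_peaks",
    "trend_matrix",
    "run_pipeline",
]


class PipelineConfig(BaseModel):
    """All tunable parameters of one pipeline run.

    Tolerances reflect unit-resolution ion-trap data; the networking
    thresholds (cosine 0.7, 4 matched fragments, minimum cluster size 2)
    and the MW windows (1 Da, 2 Da for chlorinated peaks) are the standard
    screening settings this pipeline is built around.
    """

    input_dir: Path
    catalog: Path
    out_dir: Path = Path("mycoderep-out")
    groups: tuple[str, ...] = GROUPS
    axenic_groups: tuple[str, ...] = ("G1", "G2")
    mz_tol: float = Field(0.3, gt=0)
    rt_tol: float = Field(0.5, gt=0)
    frag_tol: float = Field(0.3, gt=0)
    uv_tol: float = Field(15.0, gt=0)
    cosine_min: float = Field(0.7, ge=0, le=1)
    min_matched: int = Field(4, ge=1)
    min_cluster: int = Field(2, ge=1)
    min_fold: float = Field(2.0, gt=1)
    detect_floor: float = Field(0.0, ge=0)
    genus: str = "Aspergillus"
    seed: int = 0

    model_config = {"frozen": True}

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = json.loads(self.model_dump_json())
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def attribute_references(
    table: FeatureTable,
    axenic_groups: Sequence[str] = ("G1", "G2"),
    detect_floor: float = 0.0,
) -> dict[str, tuple[str, ...]]:
    """Assign each peak to the axenic reference(s) whose culture produced it.

    A peak detected in an axenic group is compared against that group; one
    detected in both is reported against both (shared metabolite); one
    detected in neither (co-culture-only) is compared against every axenic
    reference, under which it shows up as NEW.
    """
    out: dict[str, tuple[str, ...]] = {}
    for pid in table.peak_ids:
        refs = tuple(
            g for g in axenic_groups if table.area(pid, g) > detect_floor
        )
        out[pid] = refs or tuple(axenic_groups)
    return out


def differential_peaks(
    table: FeatureTable,
    co_groups: Sequence[str] = ("G3", "G4", "G5", "G6", "G7"),
    axenic_groups: Sequence[str] = ("G1", "G2"),
    min_fold: float = 2.0,
    detect_floor: float = 0.0,
) -> list[str]:
    """Differential selection with per-peak axenic attribution.

    A peak counts once no matter how many references or groups qualify it.
    """
    refs_by_peak = attribute_references(table, axenic_groups, detect_floor)
    selected = []
    for pid in table.peak_ids:
        hit = False
        for ref in refs_by_peak[pid]:
            for group in co_groups:
                fc = fold_change(table, pid, group, ref, detect_floor)
                if fc is None:
                    continue
                if isinstance(fc, NewMetabolite) or fc >= min_fold or fc <= 1.0 / min_fold:
                    hit = True
                    break
            if hit:
                break
        if hit:
            selected.append(pid)
    return selected


def trend_matrix(
    table: FeatureTable,
    co_groups: Sequence[str] = ("G3", "G4", "G5", "G6", "G7"),
    axenic_groups: Sequence[str] = ("G1", "G2"),
    detect_floor: float = 0.0,
    new_abundance_threshold: float | None = None,
    peak_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide fold/trend matrix: one row per (reference, peak), co-culture columns.

    Cells hold the fold rounded to two decimals, ``NEW(area)`` markers for
    metabolites absent from the reference, or blank when undetected in both.
    """
    refs_by_peak = attribute_references(table, axenic_groups, detect_floor)
    if new_abundance_threshold is None:
        areas = [
            table.area(p, g)
            for p in table.peak_ids
            for g in table.groups
            if table.area(p, g) > 0
        ]
        new_abundance_threshold = float(pd.Series(areas).median()) if areas else float("inf")
    rows = []
    for pid in peak_ids if peak_ids is not None else table.peak_ids:
        row_meta = table.row(pid)
        for ref in refs_by_peak[pid]:
            rec = {
                "reference": ref,
                "peak_id": pid,
                "mz": round(row_meta.mz, 2),
                "rt": round(row_meta.rt, 2),
            }
            for group in co_groups:
                fc = fold_change(table, pid, group, ref, detect_floor)
                if fc is None:
                    rec[group] = ""
                elif isinstance(fc, NewMetabolite):
                    cat = classify_trend(fc, new_abundance_threshold)
                    rec[group] = f"{cat.value}({fc.area:.3g})"
                else:
                    cat = classify_trend(fc, new_abundance_threshold)
                    rec[group] = f"{fc:.2f} [{cat.value}]"
            rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] = ("trends", "derep", "network"),
) -> dict[str, Path]:
    """Run the analysis and write the report bundle.

    ``stages`` selects which artifacts are written ("trends", "derep",
    "network"); alignment and differential selection always run since every
    stage depends on them.  Returns {artifact name: path}.  Raises
    FileNotFoundError / ValueError on missing or schema-violating inputs
    (the CLI maps these to exit code 2).
    """
    unknown = set(stages) - {"trends", "derep", "network"}
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    catalog = read_catalog(config.catalog)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    features = {}
    spectra = {}
    for group in config.groups:
        fpath = input_dir / f"features_{group}.csv"
        if not fpath.exists():
            raise FileNotFoundError(f"missing feature list: {fpath}")
        features[group] = read_feature_csv(fpath, group_id=group)
        spath = input_dir / f"spectra_{group}.mgf"
        spectra[group] = read_mgf(spath, group_id=group) if spath.exists() else []

    table = align_features(features, mz_tol=config.mz_tol, rt_tol=config.rt_tol)
    selected = differential_peaks(
        table,
        axenic_groups=config.axenic_groups,
        min_fold=config.min_fold,
        detect_floor=config.detect_floor,
    )
    if not selected:
        import warnings

        warnings.warn("no differential peaks selected; reports will be empty")

    artifacts: dict[str, Path] = {}
    if "trends" in stages:
        matrix = trend_matrix(
            table,
            axenic_groups=config.axenic_groups,
            detect_floor=config.detect_floor,
            peak_ids=selected,
        )
        matrix_path = out_dir / "trend_matrix.csv"
        matrix.to_csv(matrix_path, index=False)
        artifacts["trend_matrix"] = matrix_path

    if "derep" in stages:
        hits = []
        for pid in selected:
            row = table.row(pid)
            hits.extend(
                annotate_peak(
                    peak_id=pid,
                    mz=row.mz,
                    adduct=row.adduct if row.adduct != "unknown" else "[M+H]+",
                    catalog=catalog,
                    genus=config.genus,
                    uv_measured=row.uv_maxima,
                    isotope_cluster=row.isotope_cluster,
                    uv_tol=config.uv_tol,
                )
            )
        annotation_path = out_dir / "annotations.csv"
        annotation_report(hits).to_csv(annotation_path, index=False)
        artifacts["annotations"] = annotation_path

    for polarity in ("positive", "negative") if "network" in stages else ():
        pol_spectra = [
            s for group in config.groups for s in spectra[group] if s.polarity == polarity
        ]
        network = build_network(
            pol_spectra,
            cosine_min=config.cosine_min,
            min_matched=config.min_matched,
            min_cluster=config.min_cluster,
            frag_tol=config.frag_tol,
            polarity=polarity,
        )
        network = split_nodes_by_rt(
            network,
            rt_tol=config.rt_tol,
            cosine_min=config.cosine_min,
            min_matched=config.min_matched,
            frag_tol=config.frag_tol,
        )
        path = out_dir / f"network_{polarity}.graphml"
        write_graphml(network, path)
        artifacts[f"network_{polarity}"] = path

    log = {
        "mycoderep_version": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "pydantic": pydantic.__version__,
        "parameters": json.loads(PipelineConfig.model_dump_json(config)),
        "n_peaks_aligned": len(table),
        "n_peaks_selected": len(selected),
        "selected_peaks": selected,
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
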