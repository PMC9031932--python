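"""Seeded synthetic seven-group co-culture experiments with ground truth.

The generator emulates the structure of a two-strain fungal co-culture
metabolomics study: two axenic references (G1, G2) and five co-culture
regimes (G3-G7), each yielding a chromatographic feature list and an MS/MS
spectrum collection.  Every synthetic metabolite carries per-group
abundance multipliers drawn from the categorical fold magnitudes such
experiments report, so the default scenario exercises every trend category:
a metabolite suppressed when its producer is inoculated late, a
statin-like metabolite strongly induced in co-culture, a dichlorinated
metabolite appearing ONLY under co-culture stress, a trichlorinated
depsidone-like main metabolite that declines, an isomer pair sharing
precursor and fragments at distant retention times, and near-stable
background metabolites.

Noise model: multiplicative log-normal intensity noise (configurable CV),
Gaussian m/z and retention-time jitter, and random MS/MS peak dropout.
Everything is driven by one integer seed; fixed (config, seed) gives
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem_mass import average_mass, parse_formula, theoretical_envelope, IsotopeEnvelope
from .dereplication import ADDUCT_SHIFTS, CandidateRecord, write_catalog
from .spectra_features import (
    GROUPS,
    ChromatographicFeature,
    FragmentSpectrum,
    NewMetabolite,
    TrendCategory,
    classify_trend,
    write_feature_csv,
    write_mgf,
)

__all__ = [
    "ScenarioConfig",
    "SyntheticMetabolite",
    "GroundTruth",
    "SyntheticExperiment",
    "default_scenario_metabolites",
    "generate_experiment",
    "expected_category",
    "expected_differential_ids",
    "match_table_to_truth",
    "evaluate_trend_recovery",
    "evaluate_halogen_recovery",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Noise levels and scenario size.

    Defaults reflect unit-resolution ion-trap LC-MS data: m/z jitter well
    below the 0.3 Da alignment tolerance, retention jitter well below
    0.5 min, and a 10% intensity CV typical of integrated peak areas from
    replicate fungal fermentations.
    """

    n_background: int = 4
    rt_jitter_sd: float = 0.05  # minutes
    mz_jitter_sd: float = 0.02  # Da
    intensity_cv: float = 0.10
    ms2_peak_dropout: float = 0.10
    new_abundance_threshold: float = 1.0e6  # area units splitting NEW major/minor

    def __post_init__(self) -> None:
        if self.rt_jitter_sd < 0 or self.mz_jitter_sd < 0 or self.intensity_cv < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.ms2_peak_dropout < 1:
            raise ValueError("ms2_peak_dropout must be in [0, 1)")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


@dataclass(frozen=True)
class SyntheticMetabolite:
    """Ground-truth description of one planted metabolite."""

    met_id: str
    name: str
    neutral_mass: float
    adduct: str
    polarity: str
    rt: float
    n_cl: int
    multipliers: Mapping[str, float]  # group -> abundance multiplier (0 = absent)
    base_area: float
    producer_reference: str  # axenic group the fold is computed against
    formula: str = ""
    uv_maxima: tuple[float, ...] | None = None
    template_id: str = ""  # metabolites sharing this share MS/MS fragments
    new_major_groups: tuple[str, ...] = ()

    @property
    def mz(self) -> float:
        return self.neutral_mass + ADDUCT_SHIFTS[self.adduct]


@dataclass(frozen=True)
class GroundTruth:
    metabolites: tuple[SyntheticMetabolite, ...]
    seed: int
    config: ScenarioConfig


@dataclass(frozen=True)
class SyntheticExperiment:
    features: Mapping[str, Sequence[ChromatographicFeature]]
    spectra: Mapping[str, Sequence[FragmentSpectrum]]
    catalog: tuple[CandidateRecord, ...]
    truth: GroundTruth


def _from_formula(formula: str) -> float:
    return round(average_mass(parse_formula(formula)), 2)


def default_scenario_metabolites(n_background: int = 4) -> tuple[SyntheticMetabolite, ...]:
    """The default planted metabolite panel.

    Multipliers are chosen from the categorical fold magnitudes seen in
    two-strain co-culture screens (strong suppression ~0.01-0.14, moderate
    ~0.3-0.7, induction ~1.6-10.5) and deliberately avoid the category
    boundaries 0.2, 1 and 5 so that the 10% intensity CV cannot flip a
    cell's true trend class.
    """
    mets = [
        SyntheticMetabolite(
            met_id="M1",
            name="syn-diketopiperazine",
            neutral_mass=_from_formula("C16H28N4O2"),
            formula="C16H28N4O2",
            adduct="[M+H]+",
            polarity="positive",
            rt=1.7,
            n_cl=0,
            multipliers={"G2": 1.0, "G3": 0.14, "G4": 0.005, "G5": 0.02, "G6": 0.13, "G7": 1.58},
            base_area=4.0e6,
            producer_reference="G2",
            uv_maxima=(232.0,),
        ),
        SyntheticMetabolite(
            met_id="M2",
            name="syn-shared-triterpenoid",
            neutral_mass=_from_formula("C36H54O12"),
            formula="C36H54O12",
            adduct="[M+H]+",
            polarity="positive",
            rt=2.9,
            n_cl=0,
            multipliers={"G1": 1.0, "G2": 1.3, "G3": 1.6, "G4": 1.8, "G5": 2.1, "G6": 2.24, "G7": 2.46},
            base_area=3.0e6,
            producer_reference="G1",
            uv_maxima=(231.0,),
        ),
        SyntheticMetabolite(
            met_id="M3",
            name="syn-statin",
            neutral_mass=_from_formula("C24H36O5"),
            formula="C24H36O5",
            adduct="[M+Na]+",
            polarity="positive",
            rt=11.8,
            n_cl=0,
            multipliers={"G2": 1.0, "G3": 0.52, "G4": 0.08, "G5": 8.41, "G6": 7.31, "G7": 10.47},
            base_area=2.5e6,
            producer_reference="G2",
            uv_maxima=(231.0, 238.0, 247.0),
        ),
        SyntheticMetabolite(
            met_id="M4",
            name="syn-cyclopeptide",
            neutral_mass=_from_formula("C40H54N8O7"),
            formula="C40H54N8O7",
            adduct="[M+H]+",
            polarity="positive",
            rt=7.8,
            n_cl=0,
            multipliers={"G1": 1.0, "G3": 3.65, "G4": 3.48, "G5": 0.78, "G6": 0.09, "G7": 0.14},
            base_area=5.0e6,
            producer_reference="G1",
            uv_maxima=(230.0, 280.0),
        ),
        SyntheticMetabolite(
            met_id="M5",
            name="syn-trichlorodepsidone",
            neutral_mass=_from_formula("C20H17Cl3O5"),
            formula="C20H17Cl3O5",
            adduct="[M-H]-",
            polarity="negative",
            rt=13.5,
            n_cl=3,
            multipliers={"G1": 1.0, "G3": 0.3, "G4": 0.56, "G5": 0.5, "G6": 0.14, "G7": 0.0},
            base_area=6.0e6,
            producer_reference="G1",
            uv_maxima=(237.0, 264.0),
        ),
        SyntheticMetabolite(
            met_id="M6",
            name="syn-dichloro-stress-metabolite",
            neutral_mass=_from_formula("C18H18Cl2O4"),
            formula="C18H18Cl2O4",
            adduct="[M-H]-",
            polarity="negative",
            rt=11.5,
            n_cl=2,
            multipliers={"G5": 0.08, "G6": 1.0, "G7": 0.15},
            base_area=2.0e6,
            producer_reference="G1",  # absent in the reference: NEW in co-culture
            uv_maxima=(244.0, 275.0, 313.0, 361.0),
            new_major_groups=("G6",),
        ),
        SyntheticMetabolite(
            met_id="M7a",
            name="syn-isomer-early",
            neutral_mass=363.42,
            adduct="[M+H]+",
            polarity="positive",
            rt=4.0,
            n_cl=0,
            multipliers={"G2": 1.0, "G3": 2.2, "G4": 1.4, "G7": 0.7},
            base_area=1.8e6,
            producer_reference="G2",
            template_id="isomer-pair",
        ),
        SyntheticMetabolite(
            met_id="M7b",
            name="syn-isomer-late",
            neutral_mass=363.42,
            adduct="[M+H]+",
            polarity="positive",
            rt=12.0,
            n_cl=0,
            multipliers={"G2": 1.0, "G5": 1.3, "G6": 0.3},
            base_area=1.6e6,
            producer_reference="G2",
            template_id="isomer-pair",
        ),
    ]
    # Near-stable background metabolites: folds inside (1/2, 2), sitting
    # halfway (log scale) between neutrality and the selection boundary so
    # a 10% CV flips neither their trend class nor their selection status.
    bg_mults = [0.7, 1.4, 0.72, 1.38, 0.68, 1.42]
    for i in range(n_background):
        ref = "G1" if i % 2 == 0 else "G2"
        m = bg_mults[i % len(bg_mults)]
        mults = {ref: 1.0}
        for g in ("G3", "G4", "G5", "G6", "G7"):
            mults[g] = m
        mets.append(
            SyntheticMetabolite(
                met_id=f"B{i + 1}",
                name=f"syn-background-{i + 1}",
                neutral_mass=500.0 + 37.0 * i,
                adduct="[M+H]+",
                polarity="positive",
                rt=3.5 + 1.7 * i,
                n_cl=0,
                multipliers=mults,
                base_area=1.0e6 + 2.0e5 * i,
                producer_reference=ref,
            )
        )
    return tuple(mets)


def _template_rng(key: str) -> np.random.Generator:
    # stable across processes (unlike hash()); independent of the run seed
    return np.random.default_rng(zlib.crc32(key.encode()) % (2**31))


def _fragment_template(met: SyntheticMetabolite, n_peaks: int = 8) -> np.ndarray:
    """Deterministic per-metabolite fragment template: (mz, rel_intensity)."""
    rng = _template_rng(met.template_id or met.met_id)
    lo, hi = 60.0, max(90.0, met.mz - 18.0)
    mzs = np.sort(rng.uniform(lo, hi, size=n_peaks))
    # enforce >1 Da separation so templates survive 0.3 Da tolerance matching
    for i in range(1, n_peaks):
        if mzs[i] - mzs[i - 1] < 1.2:
            mzs[i] = mzs[i - 1] + 1.2
    intensities = rng.uniform(0.1, 1.0, size=n_peaks)
    intensities[rng.integers(0, n_peaks)] = 1.0
    return np.column_stack([mzs, intensities])


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1 + cv**2)))
    return float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))


def generate_experiment(
    config: ScenarioConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    metabolites: Sequence[SyntheticMetabolite] | None = None,
) -> SyntheticExperiment:
    """Generate one synthetic seven-group experiment.

    Returns in-memory features/spectra/catalog plus the ground truth; when
    ``out_dir`` is given, also writes ``features_<G>.csv``,
    ``spectra_<G>.mgf``, ``catalog.csv`` and ``scenario.txt`` in the schemas
    the pipeline consumes.
    """
    config = config or ScenarioConfig()
    mets = tuple(metabolites) if metabolites is not None else default_scenario_metabolites(
        config.n_background
    )
    if not mets:
        raise ValueError("scenario must contain at least one metabolite")
    rng = np.random.default_rng(seed)
    features: dict[str, list[ChromatographicFeature]] = {g: [] for g in GROUPS}
    spectra: dict[str, list[FragmentSpectrum]] = {g: [] for g in GROUPS}

    for met in mets:
        template = _fragment_template(met)
        for group in GROUPS:
            mult = met.multipliers.get(group, 0.0)
            if mult <= 0:
                continue
            area = met.base_area * mult * _lognormal_factor(rng, config.intensity_cv)
            mz = met.mz + rng.normal(0.0, config.mz_jitter_sd)
            rt = max(0.1, met.rt + rng.normal(0.0, config.rt_jitter_sd))
            cluster = None
            if met.n_cl > 0:
                ideal = theoretical_envelope(met.n_cl, base_mass=mz)
                noisy = [
                    (m, i * _lognormal_factor(rng, config.intensity_cv))
                    for m, i in ideal.peaks
                ]
                top = max(i for _, i in noisy)
                cluster = IsotopeEnvelope(
                    peaks=tuple((m, i / top) for m, i in noisy), spacing=2.0
                )
            features[group].append(
                ChromatographicFeature(
                    mz=mz,
                    retention_time=rt,
                    adduct=met.adduct,
                    area=area,
                    uv_maxima=met.uv_maxima,
                    isotope_cluster=cluster,
                    group_id=group,
                )
            )
            # one MS/MS scan per detected feature
            keep = rng.random(len(template)) >= config.ms2_peak_dropout
            if keep.sum() < min(4, len(template)):
                keep[:] = True
            peaks = []
            for (fmz, fint), kept in zip(template, keep):
                if not kept:
                    continue
                peaks.append(
                    (
                        fmz + rng.normal(0.0, config.mz_jitter_sd),
                        fint * area * 1e-2 * _lognormal_factor(rng, config.intensity_cv),
                    )
                )
            spectra[group].append(
                FragmentSpectrum(
                    spectrum_id=f"{met.met_id}:{group}",
                    precursor_mz=mz,
                    polarity=met.polarity,
                    retention_time=rt,
                    peaks=tuple(peaks),
                    group_id=group,
                )
            )

    catalog = _build_catalog(mets)
    truth = GroundTruth(metabolites=mets, seed=seed, config=config)
    experiment = SyntheticExperiment(
        features=features, spectra=spectra, catalog=catalog, truth=truth
    )
    if out_dir is not None:
        _write_experiment(experiment, Path(out_dir))
    return experiment


def _build_catalog(mets: Sequence[SyntheticMetabolite]) -> tuple[CandidateRecord, ...]:
    """Candidate catalog covering the planted metabolites plus decoys."""
    strain_taxon = {"G1": "Aspergillus unguis", "G2": "Aspergillus terreus"}
    records: list[CandidateRecord] = []
    seen: set[str] = set()
    for met in mets:
        if met.name in seen:
            continue
        seen.add(met.name)
        taxon = strain_taxon.get(met.producer_reference, "Aspergillus sp.")
        if met.met_id == "M6":
            # the stress metabolite is unknown in the producing genus:
            # exercises the kingdom-level widening stage
            taxon = "Cosmospora-like fungus"
        records.append(
            CandidateRecord(
                name=met.name,
                formula=parse_formula(met.formula) if met.formula else None,
                mw=0.0 if met.formula else round(met.neutral_mass, 2),
                uv_maxima=met.uv_maxima,
                taxon=taxon,
                fungal=True,
                source_db="SYN-DB",
                record_id=f"SYN-{met.met_id}",
            )
        )
        # near decoy inside the +/-1 Da window, wrong taxon, no extra evidence
        records.append(
            CandidateRecord(
                name=f"decoy-near-{met.met_id}",
                mw=round(met.neutral_mass + 0.8, 2),
                taxon="Unrelatus genericus",
                fungal=True,
                source_db="SYN-DB",
                record_id=f"SYN-{met.met_id}-near",
            )
        )
        # far decoy outside any window
        records.append(
            CandidateRecord(
                name=f"decoy-far-{met.met_id}",
                mw=round(met.neutral_mass + 5.0, 2),
                taxon="Unrelatus genericus",
                fungal=False,
                source_db="SYN-DB",
                record_id=f"SYN-{met.met_id}-far",
            )
        )
    return tuple(records)


def _write_experiment(experiment: SyntheticExperiment, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for group in GROUPS:
        write_feature_csv(experiment.features[group], out_dir / f"features_{group}.csv")
        write_mgf(experiment.spectra[group], out_dir / f"spectra_{group}.mgf")
    write_catalog(experiment.catalog, out_dir / "catalog.csv")
    cfg = experiment.truth.config
    lines = [
        f"seed = {experiment.truth.seed}",
        f"n_background = {cfg.n_background}",
        f"rt_jitter_sd = {cfg.rt_jitter_sd}",
        f"mz_jitter_sd = {cfg.mz_jitter_sd}",
        f"intensity_cv = {cfg.intensity_cv}",
        f"ms2_peak_dropout = {cfg.ms2_peak_dropout}",
        f"new_abundance_threshold = {cfg.new_abundance_threshold}",
    ]
    (out_dir / "scenario.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ground-truth derivations used to score the pipeline
# ---------------------------------------------------------------------------

def expected_category(
    met: SyntheticMetabolite, group: str, config: ScenarioConfig | None = None
) -> TrendCategory | None:
    """True trend category of a (metabolite, co-culture group) cell."""
    ref_mult = met.multipliers.get(met.producer_reference, 0.0)
    test_mult = met.multipliers.get(group, 0.0)
    if ref_mult > 0:
        return classify_trend(round(test_mult / ref_mult, 2))
    if test_mult > 0:
        major = group in met.new_major_groups
        return TrendCategory.NEW_MAJOR if major else TrendCategory.NEW_MINOR
    return None


def expected_differential_ids(
    mets: Sequence[SyntheticMetabolite], min_fold: float = 2.0
) -> set[str]:
    """Metabolite ids that a correct pipeline must select as differential."""
    out = set()
    for met in mets:
        ref_mult = met.multipliers.get(met.producer_reference, 0.0)
        for group in ("G3", "G4", "G5", "G6", "G7"):
            test = met.multipliers.get(group, 0.0)
            if ref_mult > 0:
                fold = test / ref_mult
                if fold >= min_fold or fold <= 1.0 / min_fold:
                    out.add(met.met_id)
                    break
            elif test > 0:
                out.add(met.met_id)
                break
    return out


def match_table_to_truth(
    table, truth: GroundTruth, mz_tol: float = 0.3, rt_tol: float = 0.5
) -> dict[str, str]:
    """Map ground-truth metabolite ids onto aligned feature-table peak ids."""
    mapping: dict[str, str] = {}
    for met in truth.metabolites:
        best = None
        for pid in table.peak_ids:
            row = table.row(pid)
            d_mz = abs(row.mz - met.mz)
            d_rt = abs(row.rt - met.rt)
            if d_mz <= mz_tol and d_rt <= rt_tol:
                if best is None or (d_mz, d_rt) < best[0]:
                    best = ((d_mz, d_rt), pid)
        if best is not None:
            mapping[met.met_id] = best[1]
    return mapping


def evaluate_trend_recovery(
    experiment: SyntheticExperiment,
    mz_tol: float = 0.3,
    rt_tol: float = 0.5,
) -> tuple[int, int]:
    """Score pipeline trend categories against ground truth.

    Runs alignment and per-cell fold classification against each
    metabolite's producer reference; returns (matched cells, total cells)
    over every (metabolite, co-culture group) cell with a defined truth.
    """
    from .spectra_features import align_features, classify_trend as _classify, fold_change

    table = align_features(experiment.features, mz_tol=mz_tol, rt_tol=rt_tol)
    mapping = match_table_to_truth(table, experiment.truth, mz_tol, rt_tol)
    threshold = experiment.truth.config.new_abundance_threshold
    matched = total = 0
    for met in experiment.truth.metabolites:
        pid = mapping.get(met.met_id)
        for group in ("G3", "G4", "G5", "G6", "G7"):
            expected = expected_category(met, group)
            if expected is None:
                continue
            total += 1
            if pid is None:
                continue
            fc = fold_change(table, pid, group, met.producer_reference, detect_floor=0.0)
            if fc is None:
                continue
            if _classify(fc, new_abundance_threshold=threshold) is expected:
                matched += 1
    return matched, total


def evaluate_halogen_recovery(experiment: SyntheticExperiment) -> tuple[int, int]:
    """Classify every generated chlorinated isotope cluster; count correct calls."""
    from .chem_mass import classify_halogenation

    truth_by_key = {
        (met.met_id, g): met.n_cl
        for met in experiment.truth.metabolites
        for g in GROUPS
        if met.multipliers.get(g, 0.0) > 0
    }
    by_position = {
        met.met_id: met for met in experiment.truth.metabolites if met.n_cl > 0
    }
    correct = total = 0
    for group, feats in experiment.features.items():
        for feat in feats:
            if feat.isotope_cluster is None:
                continue
            met = min(
                by_position.values(),
                key=lambda m: abs(m.mz - feat.mz) + abs(m.rt - feat.retention_time),
            )
            total += 1
            call = classify_halogenation(feat.isotope_cluster)
            if call.n_cl == met.n_cl:
                correct += 1
    return correct, total
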