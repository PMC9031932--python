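"""Ring-opened fragment enumeration for cyclic peptides.

Under low-energy CID a protonated cyclic peptide opens at an amide bond and
then sheds residues, producing b-type acylium series from every opening
position.  Because the ring can open anywhere, the observable fragment set
is the union over all ring openings of all contiguous sub-sequences.  The
neutral peptide mass of a cyclic peptide is simply the residue-mass sum (no
terminal water).  Matching the enumerated masses against an MS/MS spectrum
yields a composition-coverage figure used to support cyclopeptide
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .spectra_features import FragmentSpectrum

__all__ = [
    "PROTON_MASS",
    "Residue",
    "CyclicPeptide",
    "TheoreticalFragment",
    "enumerate_fragments",
    "match_fragments",
    "FragmentMatchResult",
    "read_residue_csv",
]

PROTON_MASS = 1.00728


@dataclass(frozen=True)
class Residue:
    label: str
    mass: float  # monoisotopic residue mass, Da

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"residue {self.label!r} must have positive mass")


@dataclass(frozen=True)
class CyclicPeptide:
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a cyclic peptide needs at least 2 residues")

    @property
    def neutral_mass(self) -> float:
        return sum(r.mass for r in self.residues)

    @property
    def protonated_mass(self) -> float:
        return self.neutral_mass + PROTON_MASS


@dataclass(frozen=True)
class TheoreticalFragment:
    mz: float
    labels: tuple[str, ...]  # all residue paths collapsing onto this mass

    @property
    def label(self) -> str:
        return "|".join(self.labels)


def enumerate_fragments(
    peptide: CyclicPeptide,
    charge_carrier: float = PROTON_MASS,
    merge_tol: float = 1e-4,
) -> list[TheoreticalFragment]:
    """All b-type ring-opened fragment m/z values plus the intact [M+H]+.

    For every opening position and every contiguous run of 1..n-1 residues
    the fragment mass is the residue-sum plus the charge carrier.  Masses
    within ``merge_tol`` merge into one entry with combined labels, so the
    result holds at most n(n-1)+1 distinct compositions.
    """
    residues = peptide.residues
    n = len(residues)
    raw: list[tuple[float, str]] = []
    for start in range(n):
        for length in range(1, n):
            run = [residues[(start + i) % n] for i in range(length)]
            mass = sum(r.mass for r in run) + charge_carrier
            raw.append((mass, "-".join(r.label for r in run)))
    raw.append((peptide.neutral_mass + charge_carrier, "[M+H]+"))
    raw.sort()
    merged: list[tuple[float, list[str]]] = []
    for mass, label in raw:
        if merged and abs(mass - merged[-1][0]) <= merge_tol:
            if label not in merged[-1][1]:
                merged[-1][1].append(label)
        else:
            merged.append((mass, [label]))
    return [TheoreticalFragment(mz=m, labels=tuple(labels)) for m, labels in merged]


@dataclass(frozen=True)
class FragmentMatchResult:
    matches: tuple[tuple[float, TheoreticalFragment], ...]  # (observed mz, fragment)
    coverage: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"observed_mz": mz, "theoretical_mz": f.mz, "labels": f.label}
                for mz, f in self.matches
            ]
        )


def match_fragments(
    spectrum: FragmentSpectrum,
    fragments: Sequence[TheoreticalFragment],
    tol: float = 0.3,
) -> FragmentMatchResult:
    """Pair observed peaks with the nearest theoretical fragment within tol.

    Coverage is the fraction of distinct theoretical compositions that found
    at least one observed peak.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be > 0")
    if not fragments:
        raise ValueError("empty theoretical fragment list")
    matches = []
    hit_fragments = set()
    for mz, _ in spectrum.peaks:
        best = min(fragments, key=lambda f: abs(f.mz - mz))
        if abs(best.mz - mz) <= tol:
            matches.append((mz, best))
            hit_fragments.add(best.mz)
    coverage = len(hit_fragments) / len(fragments)
    return FragmentMatchResult(matches=tuple(matches), coverage=coverage)


def read_residue_csv(path: str | Path) -> CyclicPeptide:
    """Residue list CSV (columns: label, mass) -> CyclicPeptide."""
    df = pd.read_csv(path)
    return CyclicPeptide(
        residues=tuple(Residue(str(r["label"]), float(r["mass"])) for _, r in df.iterrows())
    )
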