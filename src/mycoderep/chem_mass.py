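"""Molecular formulas, masses and chlorine isotope-envelope classification.

Chlorine occurs naturally as two stable isotopes roughly 2 Da apart
(35Cl/37Cl close to 3:1), so a molecule carrying *n* chlorine atoms shows a
characteristic M, M+2, ..., M+2n satellite cluster whose intensities follow
the binomial distribution over 37Cl incorporations.  Matching an observed
isotope cluster against these binomial templates is a cheap, instrument-
agnostic way to count chlorines on an unknown metabolite before any
database work, and it is the basis of the ``classify_halogenation`` call
used by the dereplication stage.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MolecularFormula",
    "IsotopeEnvelope",
    "HalogenCall",
    "FormulaError",
    "EnvelopeError",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "theoretical_envelope",
    "envelope_integer_ratios",
    "classify_halogenation",
    "ATOMIC_WEIGHTS",
    "MONOISOTOPIC_MASSES",
]


def _load_isotope_table() -> dict:
    with resources.files("mycoderep.data").joinpath("isotopes.json").open() as fh:
        return json.load(fh)


_TABLE = _load_isotope_table()
ATOMIC_WEIGHTS: Mapping[str, float] = _TABLE["atomic_weights"]
MONOISOTOPIC_MASSES: Mapping[str, float] = _TABLE["monoisotopic_masses"]
CL35_MASS: float = _TABLE["chlorine"]["mass_35"]
CL_ISOTOPE_SPACING: float = _TABLE["chlorine"]["mass_37"] - _TABLE["chlorine"]["mass_35"]

#: Default 35Cl:37Cl abundances.  The exact natural values are 0.7576/0.2424;
#: the 3:1 simplification is what produces the textbook smallest-integer
#: cluster ratios (9:6:1 for Cl2, 27:27:9:1 for Cl3) and is the default here.
#: Pass ``abundance_ratio=(0.7576, 0.2424)`` for the exact distribution.
DEFAULT_CL_ABUNDANCE: tuple[float, float] = (0.75, 0.25)


class FormulaError(ValueError):
    """Raised for unparseable or unsupported molecular formulas."""


class EnvelopeError(ValueError):
    """Raised when an observed isotope cluster cannot be classified."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral molecule, e.g. C40H54N8O7."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("empty molecular formula")
        for element, count in self.counts.items():
            if element not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unsupported element symbol: {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {element} must be a positive integer")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __str__(self) -> str:
        parts = []
        for element in sorted(self.counts, key=lambda e: (e != "C", e != "H", e)):
            n = self.counts[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    @property
    def n_cl(self) -> int:
        return self["Cl"]


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-like formula string such as ``"C20H17Cl3O5"``.

    A missing count means 1.  Raises :class:`FormulaError` on empty input,
    malformed text, or element symbols outside the supported set.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        element, digits = match.groups()
        if element not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unsupported element symbol: {element!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r}")
    return MolecularFormula(counts)


def _mass(formula: MolecularFormula | str, table: Mapping[str, float]) -> float:
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(count * table[el] for el, count in formula.counts.items())


def average_mass(formula: MolecularFormula | str) -> float:
    """Average (isotope-abundance weighted) molecular mass in Da."""
    return _mass(formula, ATOMIC_WEIGHTS)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic mass in Da (most abundant isotope of every element)."""
    return _mass(formula, MONOISOTOPIC_MASSES)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Ordered isotopologue cluster: (mass, base-peak-normalised intensity).

    ``spacing`` is the nominal Da gap between successive peaks; 2.0 for
    halogen M+2 clusters.
    """

    peaks: tuple[tuple[float, float], ...]
    spacing: float = 2.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise EnvelopeError("envelope must contain at least one peak")
        masses = [m for m, _ in self.peaks]
        intensities = [i for _, i in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise EnvelopeError("envelope masses must be strictly increasing")
        if any(i <= 0 for i in intensities) or not math.isclose(
            max(intensities), 1.0, abs_tol=1e-9
        ):
            raise EnvelopeError("intensities must lie in (0, 1] with max == 1")
        object.__setattr__(self, "peaks", tuple((float(m), float(i)) for m, i in self.peaks))

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class HalogenCall:
    """Result of matching an observed cluster against Cl_n templates."""

    n_cl: int
    score: float
    alternatives: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(score > self.score + 1e-12 for _, score in self.alternatives):
            raise ValueError("reported n_cl must carry the best score")


def _binomial_probabilities(n_cl: int, abundance_ratio: tuple[float, float]) -> list[float]:
    p35, p37 = abundance_ratio
    if p35 <= 0 or p37 <= 0:
        raise ValueError("isotope abundances must be positive")
    if not math.isclose(p35 + p37, 1.0, abs_tol=1e-9):
        raise ValueError("isotope abundances must sum to 1")
    return [math.comb(n_cl, k) * p35 ** (n_cl - k) * p37**k for k in range(n_cl + 1)]


def theoretical_envelope(
    n_cl: int,
    abundance_ratio: tuple[float, float] = DEFAULT_CL_ABUNDANCE,
    base_mass: float = 0.0,
) -> IsotopeEnvelope:
    """Binomial chlorine isotope envelope for a species with ``n_cl`` Cl atoms.

    Returns n_cl + 1 peaks at ``base_mass + 2k`` Da (k = number of 37Cl),
    intensities normalised to the base peak.  Isotopes of C/H/N/O are not
    modelled; at unit resolution their contribution to the M+2 ratios is
    below the instrument's intensity precision.
    """
    if n_cl < 0:
        raise ValueError("n_cl must be non-negative")
    probs = _binomial_probabilities(n_cl, abundance_ratio)
    top = max(probs)
    peaks = tuple(
        (base_mass + k * CL_ISOTOPE_SPACING, p / top) for k, p in enumerate(probs)
    )
    return IsotopeEnvelope(peaks=peaks, spacing=2.0)


def envelope_integer_ratios(
    n_cl: int, abundance_ratio: tuple[float, float] = DEFAULT_CL_ABUNDANCE
) -> list[int]:
    """Smallest-integer intensity ratios of the Cl_n envelope.

    With the default 3:1 abundances these are exact: Cl2 -> [9, 6, 1],
    Cl3 -> [27, 27, 9, 1].  Requires rational abundances.
    """
    p35 = Fraction(abundance_ratio[0]).limit_denominator(10**6)
    p37 = Fraction(abundance_ratio[1]).limit_denominator(10**6)
    fracs = [
        math.comb(n_cl, k) * p35 ** (n_cl - k) * p37**k for k in range(n_cl + 1)
    ]
    denom = math.lcm(*(f.denominator for f in fracs))
    ints = [int(f * denom) for f in fracs]
    divisor = math.gcd(*ints)
    return [i // divisor for i in ints]


def regularize_envelope(
    observed: IsotopeEnvelope, spacing_tol: float = 0.3
) -> IsotopeEnvelope:
    """Longest leading run of peaks with regular ~2 Da spacing.

    Weak trailing satellites near the noise floor often carry unreliable
    centroids at unit resolution; trimming them lets the cluster still be
    classified from its dominant peaks instead of being refused outright.
    """
    peaks = list(observed.peaks)
    kept = [peaks[0]]
    for prev, cur in zip(peaks, peaks[1:]):
        if abs((cur[0] - prev[0]) - 2.0) > spacing_tol:
            break
        kept.append(cur)
    top = max(i for _, i in kept)
    return IsotopeEnvelope(
        peaks=tuple((m, i / top) for m, i in kept), spacing=observed.spacing
    )


def _padded_cosine(a: Sequence[float], b: Sequence[float]) -> float:
    n = max(len(a), len(b))
    va = np.zeros(n)
    vb = np.zeros(n)
    va[: len(a)] = a
    vb[: len(b)] = b
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    if denom == 0:
        return 0.0
    return float(np.dot(va, vb) / denom)


def classify_halogenation(
    observed: IsotopeEnvelope,
    n_max: int = 4,
    abundance_ratio: tuple[float, float] = DEFAULT_CL_ABUNDANCE,
    spacing_tol: float = 0.3,
) -> HalogenCall:
    """Count chlorines by template matching against binomial envelopes.

    The observed intensity vector is compared (square-root-weighted cosine,
    zero-padded) with ``theoretical_envelope(n)`` for every n in [0, n_max];
    the best-scoring n wins, ties broken toward fewer chlorines.  The
    square-root weighting — the same convention the spectral-networking
    cosine uses — stops the base peak from dominating the score and is what
    keeps neighbouring templates (Cl2 vs Cl3) separable under realistic
    multiplicative intensity noise.  Clusters whose successive peak gaps
    deviate from 2 Da by more than ``spacing_tol`` are refused — they are
    not M+2 halogen satellites.
    """
    masses = observed.masses
    gaps = np.diff(masses)
    bad = [float(g) for g in gaps if abs(g - 2.0) > spacing_tol]
    if bad:
        raise EnvelopeError(
            f"irregular peak spacing {bad} Da; expected 2.0 +/- {spacing_tol} Da "
            "(not a halogen isotope cluster)"
        )
    obs = np.sqrt(observed.intensities)
    scored: list[tuple[int, float]] = []
    for n in range(n_max + 1):
        template = np.sqrt(theoretical_envelope(n, abundance_ratio).intensities)
        scored.append((n, _padded_cosine(obs, template)))
    # stable sort: score descending, then fewer chlorines
    scored.sort(key=lambda t: (-t[1], t[0]))
    best_n, best_score = scored[0]
    return HalogenCall(n_cl=best_n, score=best_score, alternatives=tuple(scored[1:]))
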