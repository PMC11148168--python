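"""Mass-isotopomer pattern arithmetic for GC-MS fatty-acid analysis.

Three pattern sources and one operation tie the deuterium-labelling
model together:

* the *natural* pattern of a molecular formula — the isotopologue
  envelope produced by naturally abundant ¹³C, ²H, ¹⁷O/¹⁸O etc.;
* the *deuterium* pattern — a binomial over ``N`` exchangeable hydrogen
  sites each deuterated with probability ``p`` (the body-water
  enrichment);
* their *convolution*, which is the envelope of a newly synthesised
  molecule carrying both natural isotopes and tracer deuterium.

Patterns live on a fixed ion window M+0 … M+(window-1), default five
ions (M0–M4).  Model-derived patterns are kept *unnormalised* after
truncation — probability mass beyond the window is real and must not be
reassigned — whereas observed instrument data are fractional by
construction and are window-normalised on ingestion.  Renormalisation of
model patterns happens only where they are compared with observations
(see :mod:`pericell.mida`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UnsupportedElementError

__all__ = [
    "MolecularFormula",
    "IsotopePattern",
    "DEFAULT_WINDOW",
    "ISOTOPE_ABUNDANCES",
    "nominal_mass",
    "deuterium_pattern",
    "natural_pattern",
    "convolve",
]

DEFAULT_WINDOW = 5

#: Natural isotope abundances per element, ordered by mass shift
#: (M+0, M+1, M+2, ...).  Pinned constants (IUPAC representative
#: values) rather than a mutable external table, for reproducibility.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "O": (0.99757, 0.00038, 0.00205),
    "N": (0.99636, 0.00364),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: Integer (nominal) masses of the light isotope, Da.
NOMINAL_MASSES: dict[str, int] = {"C": 12, "H": 1, "O": 16, "N": 14, "S": 32}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral molecule, e.g. methyl palmitate C17H34O2."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts or all(n == 0 for n in self.counts.values()):
            raise InvalidInputError("formula must contain at least one atom")
        for elem, n in self.counts.items():
            if n < 0:
                raise InvalidInputError(f"negative count for element {elem}")
            if elem not in ISOTOPE_ABUNDANCES:
                raise UnsupportedElementError(
                    f"no isotope data for element {elem!r} "
                    f"(supported: {sorted(ISOTOPE_ABUNDANCES)})"
                )

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        """Parse Hill-like notation such as ``"C17H34O2"``."""
        counts: dict[str, int] = {}
        pos = 0
        s = formula.strip()
        for m in _FORMULA_RE.finditer(s):
            if m.start() != pos:
                raise InvalidInputError(f"cannot parse formula {formula!r}")
            elem = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[elem] = counts.get(elem, 0) + n
            pos = m.end()
        if pos != len(s):
            raise InvalidInputError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(
            f"{e}{n}" for e, n in sorted(self.counts.items()) if n > 0
        )


@dataclass(frozen=True)
class IsotopePattern:
    """Fractional abundances over the ion window M+0 … M+k.

    ``fractions`` are non-negative; they need not sum to one (truncated
    model patterns retain their missing right tail implicitly).
    """

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise InvalidInputError("pattern window must span at least 2 ions")
        if any(f < 0 for f in self.fractions):
            raise InvalidInputError("pattern fractions must be non-negative")

    @property
    def window(self) -> int:
        return len(self.fractions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def normalised(self) -> "IsotopePattern":
        """Rescale fractions to sum to one over the window."""
        arr = self.as_array()
        total = arr.sum()
        if total <= 0:
            raise InvalidInputError("cannot normalise an all-zero pattern")
        return IsotopePattern(tuple(arr / total))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "IsotopePattern":
        return cls(tuple(float(v) for v in arr))


def nominal_mass(formula: MolecularFormula) -> int:
    """Integer mass of the all-light-isotope molecule, Da (the M+0 ion)."""
    return sum(NOMINAL_MASSES[e] * n for e, n in formula.counts.items())


def deuterium_pattern(
    p: float, n_sites: int, window: int = DEFAULT_WINDOW
) -> IsotopePattern:
    """Binomial deuterium-incorporation pattern M′x.

    ``M′x = C(N, x) p^x (1-p)^(N-x)`` for x = 0 … window-1: each of the
    ``N`` exchangeable hydrogen sites independently carries deuterium
    with probability ``p`` (the precursor water enrichment).  The
    pattern is truncated, never renormalised; ions beyond min(window,
    N+1) are structurally zero.
    """
    if not (0 <= p < 1):
        raise InvalidInputError("precursor enrichment p must lie in [0, 1)")
    if n_sites < 1:
        raise InvalidInputError("number of exchangeable sites must be >= 1")
    x = np.arange(window)
    frac = stats.binom.pmf(x, n_sites, p)
    return IsotopePattern.from_array(frac)


def _element_pattern(elem: str, count: int, window: int) -> np.ndarray:
    """Isotopologue envelope of ``count`` atoms of one element."""
    base = np.asarray(ISOTOPE_ABUNDANCES[elem], dtype=float)
    out = np.zeros(window)
    out[0] = 1.0
    acc = out
    for _ in range(count):
        acc = np.convolve(acc, base)[:window]
    return acc


def natural_pattern(
    formula: MolecularFormula, window: int = DEFAULT_WINDOW
) -> IsotopePattern:
    """Theoretical natural-abundance envelope Mx of a formula.

    Full polynomial expansion: the generating polynomial of each
    element's isotope distribution is raised to the element count and
    the per-element polynomials multiplied (Cauchy products), truncated
    to the window.  Truncation during accumulation is exact for the
    retained terms because low-order coefficients never depend on
    discarded high-order ones.
    """
    acc = np.zeros(window)
    acc[0] = 1.0
    for elem, count in formula.counts.items():
        if count:
            acc = np.convolve(acc, _element_pattern(elem, count, window))[:window]
    return IsotopePattern.from_array(acc)


def convolve(a: IsotopePattern, b: IsotopePattern) -> IsotopePattern:
    """Cauchy product of two patterns, truncated to their (equal) window.

    On the default five-ion window this is exactly the textbook
    correction of a labelling pattern for natural isotopes:
    ``Mxn = Σ_{i+j=x} M′i · Mj``.
    """
    if a.window != b.window:
        raise InvalidInputError(
            f"window mismatch: {a.window} vs {b.window}"
        )
    out = np.convolve(a.as_array(), b.as_array())[: a.window]
    return IsotopePattern.from_array(out)
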