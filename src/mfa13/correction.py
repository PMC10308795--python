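"""Correction of measured isotopologue vectors to tracer-only MIDs.

Raw MS mass-shift vectors of (fragments of) proteinogenic amino acids are
contaminated by natural isotope abundance of every element, by incomplete
tracer enrichment, and — in labelling experiments started from an unlabelled
seed culture — by residual unlabelled inoculum biomass.  The forward model is
a lower-triangular-dominant correction matrix whose column j is the expected
measured mass-shift distribution of a molecule carrying exactly j tracer
13C atoms; inversion is a non-negative least squares.

Default mode mirrors a high-resolution Orbitrap acquisition (resolution
70,000 at m/z 400) where only 13C/12C interferes with the carbon mass trace:
only carbon isotopes are convolved and correction-matrix columns sum to 1
exactly.  ``high_resolution=False`` additionally convolves the natural
isotope patterns of H, N, O, S (and P), truncated at the measured length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "FragmentFormula",
    "NATURAL_ABUNDANCE",
    "build_correction_matrix",
    "correct_mid",
    "subtract_inoculum",
]

# isotope mass-shift distributions (index = neutron shift), IUPAC 2021 values
NATURAL_ABUNDANCE: dict[str, list[float]] = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
    "P": [1.0],
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class FragmentFormula:
    """Elemental composition of a measured fragment plus its tracer-carbon count."""

    composition: dict[str, int]
    n_tracer: int | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("negative element counts")
        nc = self.composition.get("C", 0)
        if self.n_tracer is None:
            self.n_tracer = nc
        if self.n_tracer > nc:
            raise ValueError(f"n_tracer {self.n_tracer} exceeds carbon count {nc}")

    @classmethod
    def parse(cls, formula: str, n_tracer: int | None = None) -> "FragmentFormula":
        comp: dict[str, int] = {}
        rest = formula
        for el, num in _FORMULA_RE.findall(formula):
            if el:
                comp[el] = comp.get(el, 0) + (int(num) if num else 1)
                rest = rest.replace(el + num, "", 1)
        if not comp:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(comp, n_tracer)


def _convolve_truncated(a: np.ndarray, b: np.ndarray, length: int) -> np.ndarray:
    return np.convolve(a, b)[:length]


def build_correction_matrix(
    formula: FragmentFormula,
    purity: float = 1.0,
    high_resolution: bool = True,
    abundance: dict[str, list[float]] | None = None,
) -> np.ndarray:
    """(n+1)x(n+1) matrix mapping tracer MIDs to expected measured vectors.

    Column j convolves, for a molecule with exactly j tracer-13C atoms:
    tracer impurity (12C at nominally labelled positions, Binomial(j, purity)
    downward), natural 13C at the n-j untraced tracer positions and at the
    non-tracer carbons, and — in low-resolution mode — the natural isotope
    patterns of the remaining elements.  In high-resolution (carbon-only)
    mode no mass leaves the 0..n window and every column sums to 1.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    ab = abundance or NATURAL_ABUNDANCE
    n = formula.n_tracer
    n_c = formula.composition.get("C", 0)
    a13 = ab["C"][1] / (ab["C"][0] + ab["C"][1])

    # element background common to all columns
    background = np.array([1.0])
    extra_c = n_c - n
    if extra_c:
        background = np.convolve(background, binom.pmf(np.arange(extra_c + 1), extra_c, a13))
    if not high_resolution:
        for el, count in formula.composition.items():
            if el == "C" or count == 0:
                continue
            if el not in ab:
                raise ValueError(f"no natural-abundance table for element {el!r}")
            dist = np.asarray(ab[el], dtype=float)
            dist = dist / dist.sum()
            for _ in range(count):
                background = np.convolve(background, dist)

    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = binom.pmf(np.arange(j + 1), j, purity)  # actual 13C among labelled
        col = np.convolve(col, binom.pmf(np.arange(n - j + 1), n - j, a13))
        col = _convolve_truncated(col, background, n + 1)
        C[: len(col), j] = col[: n + 1]
    return C


def correct_mid(raw: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Invert the correction matrix by non-negative least squares.

    Returns the renormalized tracer-only MID and the NNLS residual norm
    (relative to the raw vector's norm) as a quality metric.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) != matrix.shape[0]:
        raise ValueError(f"raw vector length {len(raw)} != matrix dimension {matrix.shape[0]}")
    norm = np.linalg.norm(raw)
    if norm == 0:
        raise ValueError("all-zero raw isotopologue vector")
    x, resid = nnls(matrix, raw)
    total = x.sum()
    if total == 0:
        raise ValueError("NNLS returned the zero vector; raw data inconsistent with matrix")
    return x / total, float(resid / norm)


def subtract_inoculum(corrected: np.ndarray, inoculum_mid: np.ndarray, f: float) -> np.ndarray:
    """Remove the unlabelled-inoculum contribution from a corrected MID.

    The sampled biomass is a (1-f):f mixture of labelled growth and carried-
    over inoculum; inversion is (m - f*m0)/(1-f), clipped at zero and
    renormalized.  Under exponential growth f defaults to the biomass ratio
    X_inoculum / X_sampling (e.g. OD 0.025 at inoculation, OD 1 at sampling
    gives f = 0.025).
    """
    corrected = np.asarray(corrected, dtype=float)
    inoculum_mid = np.asarray(inoculum_mid, dtype=float)
    if corrected.shape != inoculum_mid.shape:
        raise ValueError("MID length mismatch")
    if not (0.0 <= f < 1.0):
        raise ValueError(f"inoculum fraction {f} outside [0, 1)")
    out = (corrected - f * inoculum_mid) / (1.0 - f)
    out = np.clip(out, 0.0, None)
    s = out.sum()
    if s == 0:
        raise ValueError("inoculum subtraction annihilated the MID")
    return out / s
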