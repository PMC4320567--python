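"""Whole-protein and sliding-window physicochemical parameters.

Covers the parameters used to contrast psychrophile and mesophile proteins:
normalized B-factor-derived flexibility (Vihinen scale), grand average of
hydropathy (Kyte–Doolittle), aromaticity, isoelectric point under a
Henderson–Hasselbalch charge model, Ikai's aliphatic index, and amino-acid
composition.  Per-position values are the arithmetic mean over a sliding
window (default 9 residues) centered on each position; unknown residues (X,
from N-containing codons) carry no scale value and are excluded from window
means and composition denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import Flex as FLEXIBILITY_SCALE
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE_SCALE

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AROMATIC = set("FWY")

# Bjellqvist pKa values (as used by common pI calculators); positive groups
# gain a proton below their pKa, negative groups lose one above it.
PKA_SETS: dict[str, dict[str, dict[str, float]]] = {
    "bjellqvist": {
        "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    },
    "emboss": {
        "positive": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    },
}

# Ikai's aliphatic-index coefficients: relative side-chain volumes of
# valine (a) and isoleucine/leucine (b) versus alanine.
ALIPHATIC_COEF_VAL = 2.9
ALIPHATIC_COEF_ILE_LEU = 3.9


@dataclass
class AminoAcidScales:
    """The residue->value tables the analysis relies on."""

    flexibility: dict[str, float] = field(default_factory=lambda: dict(FLEXIBILITY_SCALE))
    hydropathy: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE_SCALE))
    pka_set: str = "bjellqvist"


@dataclass
class ParameterProfile:
    """Windowed per-position values of one parameter plus a whole-protein summary.

    ``positions`` are 1-based center residues (w//2+1 .. L-w//2); empty when
    the protein is shorter than the window.
    """

    protein_id: str
    parameter: str
    window: int
    positions: np.ndarray
    values: np.ndarray
    whole_protein: float

    def __len__(self) -> int:
        return len(self.values)


def _window_means(per_residue: np.ndarray, w: int) -> np.ndarray:
    """Mean over each length-w window, ignoring NaN entries (reduced denominator)."""
    n = len(per_residue)
    if n < w:
        return np.empty(0)
    filled = np.nan_to_num(per_residue, nan=0.0)
    counted = (~np.isnan(per_residue)).astype(float)
    kernel = np.ones(w)
    sums = np.convolve(filled, kernel, mode="valid")
    counts = np.convolve(counted, kernel, mode="valid")
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def windowed_profile(
    sequence: str,
    scale: dict[str, float],
    w: int = 9,
    protein_id: str = "",
    parameter: str = "",
) -> ParameterProfile:
    """Sliding-window mean of a residue scale over a protein sequence."""
    if w % 2 != 1 or w < 1:
        raise ValueError("window must be a positive odd integer")
    sequence = sequence.upper()
    if len(sequence) < w:
        warnings.warn(f"sequence shorter than window ({len(sequence)} < {w}); empty profile")
        values = np.empty(0)
        positions = np.empty(0, dtype=int)
    else:
        per_residue = np.array([scale.get(r, np.nan) for r in sequence])
        values = _window_means(per_residue, w)
        positions = np.arange(w // 2 + 1, len(sequence) - w // 2 + 1)
    whole = float(np.nanmean(values)) if len(values) else float("nan")
    return ParameterProfile(
        protein_id=protein_id,
        parameter=parameter,
        window=w,
        positions=positions,
        values=values,
        whole_protein=whole,
    )


def flexibility_profile(sequence: str, w: int = 9, protein_id: str = "") -> ParameterProfile:
    """Windowed Vihinen normalized-flexibility profile (uniform window mean)."""
    return windowed_profile(
        sequence, FLEXIBILITY_SCALE, w=w, protein_id=protein_id, parameter="flexibility"
    )


def _scored(sequence: str, scale: dict[str, float]) -> list[float]:
    return [scale[r] for r in sequence.upper() if r in scale]


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value over scored residues."""
    vals = _scored(sequence, KYTE_DOOLITTLE_SCALE)
    if not vals:
        raise ValueError("no scored residues for GRAVY")
    return float(np.mean(vals))


def aromaticity(sequence: str) -> float:
    """Fraction of aromatic residues (F, W, Y) among counted residues."""
    counted = [r for r in sequence.upper() if r in set(STANDARD_RESIDUES)]
    if not counted:
        raise ValueError("empty sequence for aromaticity")
    return sum(r in AROMATIC for r in counted) / len(counted)


def composition(sequence: str) -> dict[str, float]:
    """Mole fractions of the standard residues (X excluded from the denominator)."""
    counted = [r for r in sequence.upper() if r in set(STANDARD_RESIDUES)]
    if not counted:
        raise ValueError("empty sequence for composition")
    n = len(counted)
    return {r: counted.count(r) / n for r in sorted(set(counted))}


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index from mole percentages of Ala, Val, Ile, Leu.

    AI = X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent.
    """
    comp = composition(sequence)
    return 100.0 * (
        comp.get("A", 0.0)
        + ALIPHATIC_COEF_VAL * comp.get("V", 0.0)
        + ALIPHATIC_COEF_ILE_LEU * (comp.get("I", 0.0) + comp.get("L", 0.0))
    )


def net_charge(sequence: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge of a protein at a given pH."""
    table = PKA_SETS[pka_set]
    seq = [r for r in sequence.upper() if r in set(STANDARD_RESIDUES)]
    if not seq:
        raise ValueError("empty sequence for charge computation")
    counts = {r: seq.count(r) for r in set(seq)}
    charge = 0.0
    for group, pka in table["positive"].items():
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10.0 ** (ph - pka))
    for group, pka in table["negative"].items():
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(
    sequence: str, pka_set: str = "bjellqvist", tol: float = 1e-4
) -> float:
    """pH of zero net charge, located by bisection on [0, 14].

    Net charge is monotone decreasing in pH, so bisection converges; the
    returned pH satisfies |net charge| < ``tol``.
    """
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo, pka_set) < 0:
        return lo
    if net_charge(sequence, hi, pka_set) > 0:
        return hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pka_set)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def composition_profile(
    sequence: str, residue: str, w: int = 9, protein_id: str = ""
) -> ParameterProfile:
    """Windowed fraction of one residue (indicator-scale sliding mean)."""
    residue = residue.upper()
    scale = {r: float(r == residue) for r in STANDARD_RESIDUES}
    return windowed_profile(
        sequence, scale, w=w, protein_id=protein_id, parameter=f"frac_{residue}"
    )


def gravy_profile(sequence: str, w: int = 9, protein_id: str = "") -> ParameterProfile:
    return windowed_profile(
        sequence, KYTE_DOOLITTLE_SCALE, w=w, protein_id=protein_id, parameter="gravy"
    )


def whole_protein_summary(sequence: str, w: int = 9, pka_set: str = "bjellqvist") -> dict:
    """All whole-protein parameters for one sequence."""
    return {
        "flexibility": flexibility_profile(sequence, w=w).whole_protein,
        "gravy": gravy(sequence),
        "aromaticity": aromaticity(sequence),
        "isoelectric_point": isoelectric_point(sequence, pka_set=pka_set),
        "aliphatic_index": aliphatic_index(sequence),
    }
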