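"""Molecular-formula dereplication arithmetic for ESI-MS ions.

Computes theoretical m/z values for common electrospray adducts of neutral
C/H/O molecules, ppm mass errors, and exhaustive CHO formula enumeration
within a ppm tolerance — the accurate-mass half of a dereplication workflow
for untargeted plant-metabolomics features.

Conventions: monoisotopic atomic masses; ion m/z includes the electron mass
(so [M-H]- is M minus a proton); RDBE (ring-and-double-bond equivalents)
is C - H/2 + 1 on the neutral formula, required to be a non-negative
integer for even-electron CHO species.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MASS", "PROTON_MASS", "ELECTRON_MASS", "Formula", "ADDUCTS",
    "AnnotationCandidate", "neutral_mass", "theoretical_mz", "ppm_error",
    "enumerate_cho_formulas", "annotate_features",
]

#: Monoisotopic atomic masses (Da).
MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "Na": 22.98976928,
}
PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990

_FORMATE = MASS["C"] + MASS["H"] + 2 * MASS["O"]  # HCOO radical


@dataclass(frozen=True, order=True)
class Formula:
    """A neutral CHO formula as element counts."""

    c: int
    h: int
    o: int

    def __post_init__(self) -> None:
        if self.c < 0 or self.h < 0 or self.o < 0:
            raise ValueError("element counts must be non-negative")

    @property
    def mass(self) -> float:
        return self.c * MASS["C"] + self.h * MASS["H"] + self.o * MASS["O"]

    @property
    def rdbe(self) -> float:
        return self.c - self.h / 2.0 + 1.0

    def __str__(self) -> str:
        parts = []
        for sym, n in (("C", self.c), ("H", self.h), ("O", self.o)):
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts) or "∅"


def neutral_mass(formula: Formula) -> float:
    return formula.mass


# Each adduct maps neutral mass M -> ion m/z affinely: m/z = a*M + b, with
# a = 1/|z|.  The electron mass is carried explicitly, e.g.
# [M-H]- = M - H + e = M - proton and [M-2H]2- = (M - 2*proton)/2.
ADDUCTS: Mapping[str, tuple[float, float]] = {
    "[M-H]-": (1.0, -PROTON_MASS),
    "[M+HCOO]-": (1.0, _FORMATE + ELECTRON_MASS),
    "[M-2H]2-": (0.5, -PROTON_MASS),
    "[M+H]+": (1.0, PROTON_MASS),
    "[M+Na]+": (1.0, MASS["Na"] - ELECTRON_MASS),
}


def theoretical_mz(formula: Formula, adduct: str) -> float:
    """Theoretical m/z of ``formula`` observed as ``adduct``."""
    try:
        a, b = ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {list(ADDUCTS)}")
    return a * formula.mass + b


def ppm_error(observed_mz: float, theoretical: float) -> float:
    """Relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed_mz - theoretical) / theoretical


@dataclass(frozen=True)
class AnnotationCandidate:
    """One (formula, adduct) explanation of an observed ion."""

    formula: Formula
    adduct: str
    theoretical_mz: float
    observed_mz: float
    ppm: float

    @property
    def rdbe(self) -> float:
        return self.formula.rdbe


@lru_cache(maxsize=8)
def _grid(c_max: int, h_max: int, o_max: int
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised CHO grid with even H (integer RDBE) and RDBE >= 0."""
    c = np.arange(1, c_max + 1)
    h = np.arange(0, h_max + 1, 2)  # even-electron neutral CHO: H even
    o = np.arange(0, o_max + 1)
    C, H, O = np.meshgrid(c, h, o, indexing="ij")
    C, H, O = C.ravel(), H.ravel(), O.ravel()
    ok = (C - H / 2.0 + 1.0) >= 0
    C, H, O = C[ok], H[ok], O[ok]
    masses = C * MASS["C"] + H * MASS["H"] + O * MASS["O"]
    return C, H, O, masses


def enumerate_cho_formulas(observed_mz: float, adduct: str,
                           tol_ppm: float = 5.0,
                           c_range: tuple[int, int] = (1, 60),
                           h_range: tuple[int, int] = (0, 120),
                           o_range: tuple[int, int] = (0, 40)
                           ) -> list[AnnotationCandidate]:
    """Exhaustive CHO formula search within a ppm window.

    Enumerates every formula in the ranges with integer RDBE >= 0, keeps
    those whose theoretical adduct m/z is within ``tol_ppm`` of the observed
    value, and ranks by absolute ppm error (ascending).
    """
    if adduct not in ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {list(ADDUCTS)}")
    a, b = ADDUCTS[adduct]
    C, H, O, masses = _grid(c_range[1], h_range[1], o_range[1])
    sel = (C >= c_range[0]) & (H >= h_range[0]) & (O >= o_range[0])
    theo = a * masses[sel] + b
    ppm = 1e6 * (observed_mz - theo) / theo
    hit = np.abs(ppm) <= tol_ppm
    out = [
        AnnotationCandidate(
            formula=Formula(int(c), int(h), int(o)), adduct=adduct,
            theoretical_mz=float(t), observed_mz=observed_mz, ppm=float(p))
        for c, h, o, t, p in zip(
            C[sel][hit], H[sel][hit], O[sel][hit], theo[hit], ppm[hit])
    ]
    out.sort(key=lambda cand: (abs(cand.ppm), cand.formula))
    return out


def annotate_features(features: pd.DataFrame | Iterable[tuple[str, float]],
                      adducts: Sequence[str] = ("[M-H]-", "[M+HCOO]-"),
                      tol_ppm: float = 5.0,
                      max_candidates: int | None = None) -> pd.DataFrame:
    """Formula candidates per feature, one table row per candidate.

    ``features`` is a DataFrame with a ``mz`` column (index = feature ids)
    or an iterable of (feature_id, mz) pairs.  For each feature and adduct,
    candidates within ``tol_ppm`` are listed ranked by absolute ppm error;
    ``max_candidates`` truncates the per-(feature, adduct) list.
    """
    if isinstance(features, pd.DataFrame):
        pairs = list(zip(features.index, features["mz"]))
        rt = features["rt_min"] if "rt_min" in features.columns else None
    else:
        pairs = list(features)
        rt = None
    rows = []
    for fid, mz in pairs:
        for adduct in adducts:
            cands = enumerate_cho_formulas(float(mz), adduct, tol_ppm)
            if max_candidates is not None:
                cands = cands[:max_candidates]
            for rank, cand in enumerate(cands, start=1):
                rows.append({
                    "feature_id": fid,
                    "rt_min": float(rt[fid]) if rt is not None else float("nan"),
                    "observed_mz": float(mz),
                    "adduct": adduct,
                    "formula": str(cand.formula),
                    "theoretical_mz": cand.theoretical_mz,
                    "ppm": cand.ppm,
                    "rdbe": cand.rdbe,
                    "rank": rank,
                })
    return pd.DataFrame(rows, columns=[
        "feature_id", "rt_min", "observed_mz", "adduct", "formula",
        "theoretical_mz", "ppm", "rdbe", "rank"])
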