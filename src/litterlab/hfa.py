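"""Home-field-advantage (HFA) decomposition statistics.

For a reciprocal transplant of N = 3 litter species among their three home
forests, with D(s, f) a decomposition measure for species ``s`` in forest
``f`` (mass-loss % by default), the statistic family is

    HDD_i = (D_iI - D_jI) + (D_iI - D_kI)          home decomposition difference
    ADD_i = (D_iJ - D_jJ) + (D_iK - D_kK)          away decomposition difference
    H     = (HDD_i + HDD_j + HDD_k) / (N - 1)      total HFA, all species
    ADH_i = HDD_i - ADD_i - H                      additional decomposition at home

where capital letters index forests and I is species i's home forest.
ADH_i > 0 indicates a home-field advantage, ADH_i < 0 a disadvantage.

Replicate ADH values are obtained by repeatedly assembling a 3 x 3 table from
one randomly chosen litterbag per (species x forest) cell; bags are consumed
without replacement across draws whenever enough replicates exist, so the
draws are independent and a one-sample Student t-test of the draws against
zero is exactly calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FORESTS, HOME_FOREST, SPECIES, LitterBagRecord

__all__ = [
    "compute_hdd", "compute_add", "compute_total_h", "compute_adh_table",
    "draw_adh_replicates", "adh_ttest", "hfa_analysis", "HFAResult",
]


class MissingCellError(KeyError):
    """A (species, forest) cell required by the HFA equations is absent."""


def _as_slice(cell_means) -> pd.DataFrame:
    """Coerce a 3 x 3 D slice to a DataFrame indexed species x forest."""
    if isinstance(cell_means, pd.DataFrame):
        df = cell_means
    else:
        df = pd.DataFrame(cell_means)
    try:
        df = df.loc[list(SPECIES), list(FORESTS)]
    except KeyError as exc:
        raise MissingCellError(f"missing cell in D table: {exc}") from exc
    if df.isna().any().any():
        bad = [(s, f) for s in SPECIES for f in FORESTS if pd.isna(df.at[s, f])]
        raise MissingCellError(f"missing cells in D table: {bad}")
    return df


def compute_hdd(cell_means, species_i: str) -> float:
    """Home decomposition difference of ``species_i`` in its home forest."""
    d = _as_slice(cell_means)
    home = HOME_FOREST[species_i]
    others = [s for s in SPECIES if s != species_i]
    return float(sum(d.at[species_i, home] - d.at[o, home] for o in others))


def compute_add(cell_means, species_i: str) -> float:
    """Away decomposition difference: ``species_i`` in each away forest,
    compared with the local home species there."""
    d = _as_slice(cell_means)
    total = 0.0
    for other in SPECIES:
        if other == species_i:
            continue
        away = HOME_FOREST[other]
        total += d.at[species_i, away] - d.at[other, away]
    return float(total)


def compute_total_h(hdd_values: Sequence[float] | Mapping[str, float],
                    n_species: int | None = None) -> float:
    """Total HFA across species: sum of HDD values over (N - 1)."""
    if isinstance(hdd_values, Mapping):
        vals = list(hdd_values.values())
    else:
        vals = list(hdd_values)
    n = len(vals) if n_species is None else n_species
    if n < 2:
        raise ValueError(f"need at least 2 species, got {n}")
    return float(sum(vals) / (n - 1))


def compute_adh_table(cell_means) -> pd.Series:
    """ADH for every species from a complete 3 x 3 D slice."""
    d = _as_slice(cell_means)
    hdd = {s: compute_hdd(d, s) for s in SPECIES}
    h = compute_total_h(hdd)
    adh = {s: hdd[s] - compute_add(d, s) - h for s in SPECIES}
    return pd.Series(adh, name="ADH").reindex(list(SPECIES))


def _cell_table(records: Iterable[LitterBagRecord], treatment: str,
                time_months: int, d_metric: str) -> dict[tuple[str, str], list[float]]:
    attr = "mass_loss_pct" if d_metric == "mass_loss_pct" else "remaining_mass_pct"
    cells: dict[tuple[str, str], list[float]] = {
        (s, f): [] for s in SPECIES for f in FORESTS}
    for r in records:
        if r.treatment == treatment and r.time_months == time_months:
            cells[(r.species, r.forest)].append(getattr(r, attr))
    empty = [c for c, v in cells.items() if not v]
    if empty:
        raise MissingCellError(
            f"no litterbags for cells {empty} at treatment={treatment}, "
            f"time={time_months}")
    return cells


def draw_adh_replicates(records: Iterable[LitterBagRecord], treatment: str,
                        time_months: int, n_draws: int = 12,
                        seed: int | np.random.Generator | None = None,
                        d_metric: str = "mass_loss_pct") -> pd.DataFrame:
    """Replicate ADH draws for one (treatment, time) stratum.

    Each draw assembles a 3 x 3 D table from one randomly chosen bag per
    (species x forest) cell.  Within each cell the bags are randomly permuted
    once and consumed in order, so no bag is reused while replicates last;
    if ``n_draws`` exceeds the bag count, later draws resample with
    replacement (with a warning) and the t-test loses exactness.

    Returns a DataFrame of shape (n_draws, 3) with species columns.
    """
    rng = np.random.default_rng(seed)
    cells = _cell_table(records, treatment, time_months, d_metric)
    min_bags = min(len(v) for v in cells.values())
    if n_draws > min_bags:
        warnings.warn(
            f"n_draws={n_draws} exceeds the {min_bags} bags available in the "
            "smallest cell; sampling with replacement across draws",
            stacklevel=2)
    picks = {}
    for cell, values in cells.items():
        values = np.asarray(values, dtype=float)
        order = rng.permutation(len(values))
        if n_draws <= len(values):
            chosen = order[:n_draws]
        else:
            extra = rng.integers(0, len(values), size=n_draws - len(values))
            chosen = np.concatenate([order, extra])
        picks[cell] = values[chosen]
    draws = np.empty((n_draws, len(SPECIES)))
    for d in range(n_draws):
        table = pd.DataFrame(
            [[picks[(s, f)][d] for f in FORESTS] for s in SPECIES],
            index=list(SPECIES), columns=list(FORESTS))
        draws[d] = compute_adh_table(table).to_numpy()
    return pd.DataFrame(draws, columns=list(SPECIES))


def adh_ttest(draws: Sequence[float]) -> tuple[float, float, bool]:
    """One-sample two-sided Student t-test of ADH draws against zero.

    Returns ``(t, p, degenerate)``; when the draws have zero variance the
    test is undefined and ``(nan, nan, True)`` is returned.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    if np.ptp(x) == 0.0:
        return (float("nan"), float("nan"), True)
    res = stats.ttest_1samp(x, 0.0)
    return (float(res.statistic), float(res.pvalue), False)


@dataclass
class HFAResult:
    """HFA statistics for one (species, treatment, time) combination."""

    species: str
    treatment: str
    time_months: int
    hdd: float
    add: float
    h: float
    adh: float
    draws: np.ndarray = field(repr=False)
    t_value: float = float("nan")
    p_value: float = float("nan")
    degenerate: bool = False

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def hfa_analysis(records: Sequence[LitterBagRecord], n_draws: int = 12,
                 seed: int | None = None,
                 d_metric: str = "mass_loss_pct") -> list[HFAResult]:
    """Full HFA analysis over every (treatment, time) stratum present.

    Point estimates (HDD, ADD, H, ADH) come from the cell means; the t-test
    comes from ``n_draws`` replicate one-bag-per-cell draws.
    """
    rng = np.random.default_rng(seed)
    strata = sorted({(r.treatment, r.time_months) for r in records},
                    key=lambda x: (x[1], x[0] != "ND"))
    results: list[HFAResult] = []
    for treatment, time_months in strata:
        cells = _cell_table(records, treatment, time_months, d_metric)
        means = pd.DataFrame(
            [[float(np.mean(cells[(s, f)])) for f in FORESTS] for s in SPECIES],
            index=list(SPECIES), columns=list(FORESTS))
        hdd = {s: compute_hdd(means, s) for s in SPECIES}
        h = compute_total_h(hdd)
        draws = draw_adh_replicates(
            records, treatment, time_months, n_draws=n_draws, seed=rng,
            d_metric=d_metric)
        for s in SPECIES:
            t, p, degen = adh_ttest(draws[s])
            results.append(HFAResult(
                species=s, treatment=treatment, time_months=time_months,
                hdd=hdd[s], add=compute_add(means, s), h=h,
                adh=hdd[s] - compute_add(means, s) - h,
                draws=draws[s].to_numpy(), t_value=t, p_value=p,
                degenerate=degen))
    return results


def hfa_results_to_frame(results: Sequence[HFAResult]) -> pd.DataFrame:
    """Tabulate HFA results (one row per species x treatment x time)."""
    return pd.DataFrame([{
        "treatment": r.treatment,
        "time_months": r.time_months,
        "species": r.species,
        "HDD": r.hdd,
        "ADD": r.add,
        "H": r.h,
        "ADH": r.adh,
        "t_value": r.t_value,
        "p_value": r.p_value,
        "n_draws": r.n_draws,
    } for r in results])
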