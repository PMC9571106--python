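"""Domain types, leaf-trait formulas, and CSV readers/writers.

The experimental unit is a litterbag: 10 g of senescent leaves or needles of
one species, collected under one precipitation treatment (its *litter type*),
left to decompose in one forest plot under one precipitation treatment, and
retrieved after 12 or 24 months.  Decomposition is measured as dry-mass loss.

Factor levels are fixed ASCII tokens: species ``Qilex`` / ``Qpubescens`` /
``Phalepensis``, forests named after their dominant species, and ``ND`` /
``AD`` for natural versus amplified (rain-excluded) drought.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SPECIES = ("Qilex", "Qpubescens", "Phalepensis")
FORESTS = ("Qilex_forest", "Qpubescens_forest", "Phalepensis_forest")
TREATMENTS = ("ND", "AD")
LITTER_TYPES = ("ND", "AD")
TIMES = (12, 24)

#: Forest where each species is "at home".
HOME_FOREST = dict(zip(SPECIES, FORESTS))

#: Human-readable site names of the three forests.
SITE_NAMES = {
    "Qilex_forest": "Puechabon",
    "Qpubescens_forest": "O3HP",
    "Phalepensis_forest": "Fontblanche",
}

LITTERBAG_COLUMNS = [
    "forest",
    "species",
    "litter_type",
    "treatment",
    "time_months",
    "replicate",
    "initial_dry_mass_g",
    "final_dry_mass_g",
]

TRAIT_COLUMNS = ["species", "litter_type", "trait", "value", "unit"]

TRAIT_NAMES = (
    "C", "N", "C/N", "P", "Ca", "K", "Mg", "Na",
    "phenolics", "lignin", "cellulose", "hemicellulose", "WSC", "WHC", "SLA",
)


class InvalidRecordError(ValueError):
    """A litterbag or trait record violates a domain invariant."""


@dataclass(frozen=True)
class LitterBagRecord:
    """One litterbag: design factors plus initial and final dry mass (g)."""

    forest: str
    species: str
    litter_type: str
    treatment: str
    time_months: int
    replicate: int
    initial_dry_mass_g: float
    final_dry_mass_g: float

    def __post_init__(self) -> None:
        if self.forest not in FORESTS:
            raise InvalidRecordError(f"unknown forest {self.forest!r} in {self}")
        if self.species not in SPECIES:
            raise InvalidRecordError(f"unknown species {self.species!r} in {self}")
        if self.litter_type not in LITTER_TYPES:
            raise InvalidRecordError(
                f"unknown litter_type {self.litter_type!r} in {self}")
        if self.treatment not in TREATMENTS:
            raise InvalidRecordError(
                f"unknown treatment {self.treatment!r} in {self}")
        if self.time_months not in TIMES:
            raise InvalidRecordError(
                f"time_months must be one of {TIMES}, got {self.time_months}")
        if self.initial_dry_mass_g <= 0:
            raise InvalidRecordError(
                f"initial mass must be positive in {self}")
        if not 0 <= self.final_dry_mass_g <= self.initial_dry_mass_g:
            raise InvalidRecordError(
                f"final mass must lie in [0, initial] in {self}")

    @property
    def mass_loss_pct(self) -> float:
        return mass_loss_pct(self.initial_dry_mass_g, self.final_dry_mass_g)

    @property
    def remaining_mass_pct(self) -> float:
        return remaining_mass_pct(self.initial_dry_mass_g, self.final_dry_mass_g)


@dataclass(frozen=True)
class TraitRecord:
    """One initial litter-quality measurement (Table-1 style)."""

    species: str
    litter_type: str
    trait: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidRecordError(f"unknown species {self.species!r}")
        if self.litter_type not in LITTER_TYPES:
            raise InvalidRecordError(f"unknown litter_type {self.litter_type!r}")
        if self.value < 0:
            raise InvalidRecordError(
                f"trait {self.trait!r} must be non-negative, got {self.value}")


# ---------------------------------------------------------------------------
# trait / decomposition formulas (pure functions)
# ---------------------------------------------------------------------------

def remaining_mass_pct(initial_g: float, final_g: float) -> float:
    """Remaining dry mass as a percentage of the initial dry mass."""
    if initial_g <= 0:
        raise InvalidRecordError(f"initial mass must be positive, got {initial_g}")
    if not 0 <= final_g <= initial_g:
        raise InvalidRecordError(
            f"final mass {final_g} outside [0, {initial_g}]")
    return 100.0 * final_g / initial_g


def mass_loss_pct(initial_g: float, final_g: float) -> float:
    """Mass loss percentage; exact complement of :func:`remaining_mass_pct`."""
    return 100.0 - remaining_mass_pct(initial_g, final_g)


def whc_pct(wet_weight_g: float, dry_weight_g: float) -> float:
    """Water holding capacity, (wet weight / dry weight) x 100.

    A litter sample soaked for 24 h and drained normally weighs more wet than
    dry, so WHC >= 100.  Field samples occasionally drain below dry weight;
    that yields a warning, not an error.
    """
    if dry_weight_g <= 0:
        raise InvalidRecordError(f"dry weight must be positive, got {dry_weight_g}")
    if wet_weight_g <= 0:
        raise InvalidRecordError(f"wet weight must be positive, got {wet_weight_g}")
    if wet_weight_g < dry_weight_g:
        warnings.warn(
            f"wet weight {wet_weight_g} below dry weight {dry_weight_g}; "
            "WHC below 100 suggests a drainage artifact", stacklevel=2)
    return 100.0 * wet_weight_g / dry_weight_g


def sla_cm2_per_g(leaf_area_cm2: float, leaf_dry_mass_g: float) -> float:
    """Specific leaf area: leaf area divided by leaf dry mass (cm^2/g)."""
    if leaf_area_cm2 <= 0 or leaf_dry_mass_g <= 0:
        raise InvalidRecordError(
            f"leaf area and dry mass must be positive, got "
            f"({leaf_area_cm2}, {leaf_dry_mass_g})")
    return leaf_area_cm2 / leaf_dry_mass_g


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def litterbags_to_frame(records: Iterable[LitterBagRecord]) -> pd.DataFrame:
    """Tabulate litterbag records into a DataFrame with canonical columns."""
    return pd.DataFrame(
        [[getattr(r, c) for c in LITTERBAG_COLUMNS] for r in records],
        columns=LITTERBAG_COLUMNS,
    )


def frame_to_litterbags(frame: pd.DataFrame) -> list[LitterBagRecord]:
    """Validate a DataFrame row by row into :class:`LitterBagRecord` objects.

    Raises :class:`InvalidRecordError` listing every offending row number
    (1-based, excluding the header) if any row fails validation.
    """
    missing = [c for c in LITTERBAG_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidRecordError(f"missing columns: {missing}")
    records: list[LitterBagRecord] = []
    problems: list[str] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(LitterBagRecord(
                forest=str(row["forest"]),
                species=str(row["species"]),
                litter_type=str(row["litter_type"]),
                treatment=str(row["treatment"]),
                time_months=int(row["time_months"]),
                replicate=int(row["replicate"]),
                initial_dry_mass_g=float(row["initial_dry_mass_g"]),
                final_dry_mass_g=float(row["final_dry_mass_g"]),
            ))
        except (InvalidRecordError, ValueError) as exc:
            problems.append(f"row {pos}: {exc}")
    if problems:
        raise InvalidRecordError(
            "invalid litterbag rows:\n" + "\n".join(problems))
    return records


def read_litterbag_csv(path: str | Path) -> list[LitterBagRecord]:
    """Read a litterbag CSV (comma-separated, header mandatory, UTF-8)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame_to_litterbags(frame)


def write_litterbag_csv(records: Sequence[LitterBagRecord], path: str | Path) -> None:
    litterbags_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_trait_csv(path: str | Path) -> list[TraitRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAIT_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidRecordError(f"missing columns: {missing}")
    records = []
    problems = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(TraitRecord(
                species=str(row["species"]),
                litter_type=str(row["litter_type"]),
                trait=str(row["trait"]),
                value=float(row["value"]),
                unit=str(row["unit"]),
            ))
        except (InvalidRecordError, ValueError) as exc:
            problems.append(f"row {pos}: {exc}")
    if problems:
        raise InvalidRecordError("invalid trait rows:\n" + "\n".join(problems))
    return records


def write_trait_csv(records: Sequence[TraitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [[getattr(r, c) for c in TRAIT_COLUMNS] for r in records],
        columns=TRAIT_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")
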