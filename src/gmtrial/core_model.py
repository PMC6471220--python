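"""Domain types, validation and CSV I/O for zebrafish feeding-trial data.

The tables exchanged by the pipeline are plain CSV (comma separated, UTF-8,
"." decimal separator, header row mandatory).  Units are fixed by the schema
— grams, millimetres, milligrams, days — and never auto-converted.  Missing
values are empty cells and stay missing; they are never silently zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FishRecord",
    "DietComposition",
    "PooledOrganSample",
    "FecalSample",
    "FeedRation",
    "TrialDataset",
    "SchemaError",
    "ReferentialIntegrityError",
    "ValidationError",
    "read_trial",
    "read_endpoint_table",
    "write_endpoint_table",
]

log = logging.getLogger(__name__)

SEXES = ("male", "female")
SEX_STRATA = ("male", "female", "pooled")
ORGANS = ("liver", "gonad", "muscle")
MACRONUTRIENTS = ("carbohydrate", "protein", "lipid")

#: Daily ration as a fraction of mean initial tank wet weight (2.5 %/day).
DEFAULT_RATION_FRACTION = 0.025
#: Number of fish pooled per organ sample per sex per replicate.
DEFAULT_POOL_SIZE = 10


class SchemaError(ValueError):
    """A required column is missing or has the wrong name."""


class ReferentialIntegrityError(ValueError):
    """A row references a tank or diet that does not exist."""


class ValidationError(ValueError):
    """Row values violate a type invariant."""


# --------------------------------------------------------------------------
# record types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FishRecord:
    """One fish measured at one timepoint.

    ``weight`` is body wet weight W in grams, ``fork_length`` is L in
    millimetres; both must be strictly positive.
    """

    fish_id: str
    tank_id: str
    diet_id: str
    sex: str
    day: int
    weight: float
    fork_length: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.day < 0:
            raise ValidationError(f"day must be non-negative, got {self.day}")
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0 g, got {self.weight}")
        if not self.fork_length > 0:
            raise ValidationError(
                f"fork_length must be > 0 mm, got {self.fork_length}"
            )


@dataclass(frozen=True)
class DietComposition:
    """Macronutrient content of a diet in g per 100 g diet."""

    diet_id: str
    substitution_pct: float
    dry_matter: float
    carbohydrates: float
    proteins: float
    lipids: float
    is_commercial_control: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_pct <= 100:
            raise ValidationError(
                f"substitution_pct must be in [0,100], got {self.substitution_pct}"
            )
        for name in ("dry_matter", "carbohydrates", "proteins", "lipids"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must be in [0,100] g/100 g, got {v}")
        macro = self.carbohydrates + self.proteins + self.lipids
        # small slack for assay rounding in printed compositions
        if macro > self.dry_matter + 1e-9 or self.dry_matter > 100 + 1e-9:
            raise ValidationError(
                f"diet {self.diet_id}: carbohydrates+proteins+lipids ({macro:.1f}) "
                f"must not exceed dry matter ({self.dry_matter:.1f}) nor 100"
            )


@dataclass(frozen=True)
class PooledOrganSample:
    """Pooled organ tissue from ``n_fish`` fish of one sex in one tank.

    ``total_body_weight`` is the summed wet weight of the same fish the organs
    came from; somatic indices are computed against it.
    ``component_content`` optionally carries assayed carbohydrate/protein/
    lipid masses (mg per pooled sample).
    """

    tank_id: str
    sex: str
    organ: str
    n_fish: int
    organ_weight: float
    total_body_weight: float
    component_content: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.organ not in ORGANS:
            raise ValidationError(f"organ must be one of {ORGANS}, got {self.organ!r}")
        if self.n_fish <= 0:
            raise ValidationError("n_fish must be positive")
        if self.organ_weight < 0:
            raise ValidationError("organ_weight must be >= 0 g")
        if not self.total_body_weight > 0:
            raise ValidationError("total_body_weight must be > 0 g")
        if self.organ_weight >= self.total_body_weight:
            raise ValidationError(
                f"organ_weight ({self.organ_weight} g) must be smaller than the "
                f"summed body weight ({self.total_body_weight} g)"
            )
        if self.component_content is not None:
            for k, v in self.component_content.items():
                if k not in MACRONUTRIENTS:
                    raise ValidationError(f"unknown component {k!r}")
                if v is not None and not np.isnan(v) and v < 0:
                    raise ValidationError(f"component mass {k}={v} must be >= 0 mg")


@dataclass(frozen=True)
class FecalSample:
    """Total fecal matter collected from one tank over ``collection_hours``."""

    tank_id: str
    component_mass: Mapping[str, float]
    collection_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.collection_hours <= 0:
            raise ValidationError("collection_hours must be positive")
        for k, v in self.component_mass.items():
            if k not in MACRONUTRIENTS:
                raise ValidationError(f"unknown component {k!r}")
            if v is not None and not np.isnan(v) and v < 0:
                raise ValidationError(f"fecal mass {k}={v} must be >= 0 mg")


@dataclass(frozen=True)
class FeedRation:
    """Daily feed dose of one tank, split into macronutrient masses (mg/day)."""

    tank_id: str
    component_mass_per_day: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.component_mass_per_day.items():
            if k not in MACRONUTRIENTS:
                raise ValidationError(f"unknown component {k!r}")
            if v is not None and not np.isnan(v) and v < 0:
                raise ValidationError(f"ration mass {k}={v} must be >= 0 mg/day")

    @classmethod
    def from_diet(
        cls,
        tank_id: str,
        diet: DietComposition,
        mean_initial_weight_g: float,
        n_fish: int,
        ration_fraction: float = DEFAULT_RATION_FRACTION,
    ) -> "FeedRation":
        """Ration from diet composition × daily dose mass.

        Daily dose = ``ration_fraction`` (default 2.5 %/day) of the tank's
        total initial wet weight; component masses follow the diet's g/100 g
        composition.  Returned masses are mg/day.
        """
        dose_mg = ration_fraction * mean_initial_weight_g * n_fish * 1000.0
        return cls(
            tank_id=tank_id,
            component_mass_per_day={
                "carbohydrate": dose_mg * diet.carbohydrates / 100.0,
                "protein": dose_mg * diet.proteins / 100.0,
                "lipid": dose_mg * diet.lipids / 100.0,
            },
        )


# --------------------------------------------------------------------------
# trial container
# --------------------------------------------------------------------------

FISH_COLUMNS = ["fish_id", "tank_id", "day", "sex", "weight_g", "fork_length_mm"]
TANK_COLUMNS = ["tank_id", "diet_id"]
DIET_COLUMNS = [
    "diet_id",
    "substitution_pct",
    "dry_matter",
    "carbohydrates",
    "proteins",
    "lipids",
    "is_commercial_control",
]
ORGAN_COLUMNS = [
    "tank_id",
    "sex",
    "organ",
    "n_fish",
    "organ_weight_g",
    "total_body_weight_g",
    "carbohydrate_mg",
    "protein_mg",
    "lipid_mg",
]
FECES_COLUMNS = [
    "tank_id",
    "collection_hours",
    "carbohydrate_mg",
    "protein_mg",
    "lipid_mg",
]
RATION_COLUMNS = ["tank_id", "carbohydrate_mg_day", "protein_mg_day", "lipid_mg_day"]
ENDPOINT_COLUMNS = [
    "trial_id",
    "diet_id",
    "tank_id",
    "sex_stratum",
    "endpoint_name",
    "day",
    "value",
]


@dataclass
class TrialDataset:
    """A validated feeding trial: fish, tanks, diets and assay tables.

    All tables are pandas DataFrames in the documented column dictionaries;
    ``tanks`` maps every tank to exactly one diet.
    """

    trial_id: str
    fish: pd.DataFrame
    tanks: pd.DataFrame
    diets: pd.DataFrame
    organs: pd.DataFrame = field(default_factory=lambda: _empty(ORGAN_COLUMNS))
    feces: pd.DataFrame = field(default_factory=lambda: _empty(FECES_COLUMNS))
    rations: pd.DataFrame = field(default_factory=lambda: _empty(RATION_COLUMNS))
    control_diet_id: str | None = None
    schedule: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check every invariant; raise on the first violation."""
        for frame, cols, name in (
            (self.fish, FISH_COLUMNS, "fish"),
            (self.tanks, TANK_COLUMNS, "tanks"),
            (self.diets, DIET_COLUMNS, "diets"),
            (self.organs, ORGAN_COLUMNS, "organs"),
            (self.feces, FECES_COLUMNS, "feces"),
            (self.rations, RATION_COLUMNS, "rations"),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s): {missing}")

        if self.tanks["tank_id"].duplicated().any():
            raise ValidationError("tanks table: tank_id must map to exactly one diet")
        known_tanks = set(self.tanks["tank_id"])
        known_diets = set(self.diets["diet_id"])

        orphan_diets = set(self.tanks["diet_id"]) - known_diets
        if orphan_diets:
            raise ReferentialIntegrityError(
                f"tanks reference unknown diet(s): {sorted(orphan_diets)}"
            )
        for name, frame in (
            ("fish", self.fish),
            ("organs", self.organs),
            ("feces", self.feces),
            ("rations", self.rations),
        ):
            if len(frame):
                orphans = set(frame["tank_id"]) - known_tanks
                if orphans:
                    raise ReferentialIntegrityError(
                        f"{name} table references unknown tank(s): {sorted(orphans)}"
                    )

        if self.control_diet_id is not None and self.control_diet_id not in known_diets:
            raise ReferentialIntegrityError(
                f"control diet {self.control_diet_id!r} absent from diets table"
            )

        if len(self.fish):
            bad = self.fish[
                ~(self.fish["weight_g"] > 0) | ~(self.fish["fork_length_mm"] > 0)
            ]
            if len(bad):
                raise ValidationError(
                    "non-positive weight or fork length in fish rows: "
                    f"{bad.index.tolist()[:10]}"
                )
            if self.fish["day"].lt(0).any():
                raise ValidationError("fish table contains negative days")
            dup = self.fish.duplicated(subset=["fish_id", "day"])
            if dup.any():
                raise ValidationError(
                    f"(fish_id, day) not unique: rows {self.fish.index[dup].tolist()[:10]}"
                )
            bad_sex = set(self.fish["sex"]) - set(SEXES)
            if bad_sex:
                raise ValidationError(f"unknown sex value(s): {sorted(bad_sex)}")
            if self.schedule:
                off = set(self.fish["day"]) - set(self.schedule)
                if off:
                    raise ValidationError(
                        f"fish measured on day(s) {sorted(off)} outside the "
                        f"schedule {self.schedule}"
                    )
        else:
            log.warning("trial %s: fish table is empty", self.trial_id)

        # construct one record object per row group to exercise the row-level
        # invariants (cheap relative to I/O; guarantees no partially valid
        # dataset escapes)
        for row in self.diets.itertuples(index=False):
            DietComposition(
                diet_id=row.diet_id,
                substitution_pct=float(row.substitution_pct),
                dry_matter=float(row.dry_matter),
                carbohydrates=float(row.carbohydrates),
                proteins=float(row.proteins),
                lipids=float(row.lipids),
                is_commercial_control=bool(row.is_commercial_control),
            )
        for row in self.organs.itertuples(index=False):
            PooledOrganSample(
                tank_id=row.tank_id,
                sex=row.sex,
                organ=row.organ,
                n_fish=int(row.n_fish),
                organ_weight=float(row.organ_weight_g),
                total_body_weight=float(row.total_body_weight_g),
                component_content={
                    "carbohydrate": float(row.carbohydrate_mg),
                    "protein": float(row.protein_mg),
                    "lipid": float(row.lipid_mg),
                },
            )

    # -- conveniences ------------------------------------------------------
    def tank_to_diet(self) -> dict[str, str]:
        return dict(zip(self.tanks["tank_id"], self.tanks["diet_id"]))

    def fish_at(self, day: int) -> pd.DataFrame:
        return self.fish[self.fish["day"] == day]

    @property
    def n_tanks(self) -> int:
        return len(self.tanks)


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _read_csv(path: Path, required: list[str], name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found at {path}")
    # round_trip float parsing so write -> read -> write is byte-stable
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} table {path} missing column(s): {missing}")
    log.info("read %d %s rows from %s", len(frame), name, path)
    return frame


def read_trial(
    directory: str | Path,
    trial_id: str | None = None,
    control_diet_id: str | None = None,
    schedule: tuple[int, ...] = (),
) -> TrialDataset:
    """Read a trial from a directory of CSV tables.

    Expects ``fish.csv``, ``tanks.csv`` and ``diets.csv``; ``organs.csv``,
    ``feces.csv`` and ``rations.csv`` are optional.  Returns a validated
    :class:`TrialDataset` or raises; no partially valid dataset escapes.
    """
    directory = Path(directory)
    fish = _read_csv(directory / "fish.csv", FISH_COLUMNS, "fish")
    tanks = _read_csv(directory / "tanks.csv", TANK_COLUMNS, "tanks")
    diets = _read_csv(directory / "diets.csv", DIET_COLUMNS, "diets")
    optional = {}
    for name, cols in (
        ("organs", ORGAN_COLUMNS),
        ("feces", FECES_COLUMNS),
        ("rations", RATION_COLUMNS),
    ):
        path = directory / f"{name}.csv"
        if path.exists():
            optional[name] = _read_csv(path, cols, name)
    return TrialDataset(
        trial_id=trial_id or directory.name,
        fish=fish,
        tanks=tanks,
        diets=diets,
        control_diet_id=control_diet_id,
        schedule=tuple(schedule),
        **optional,
    )


def write_trial(trial: TrialDataset, directory: str | Path) -> None:
    """Write all tables of a trial as the standard CSV set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("fish", "tanks", "diets", "organs", "feces", "rations"):
        frame = getattr(trial, name)
        frame.to_csv(directory / f"{name}.csv", index=False)


def write_endpoint_table(table, path: str | Path) -> None:
    """Serialize an endpoint table to CSV (one row per tank × stratum × endpoint).

    Missing endpoint values become empty cells; the table round-trips
    losslessly through :func:`read_endpoint_table` at full float precision.
    """
    frame = getattr(table, "frame", table)
    if frame is None or len(frame) == 0:
        raise ValidationError("refusing to write an empty endpoint table")
    missing = [c for c in ENDPOINT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"endpoint table missing column(s): {missing}")
    frame[ENDPOINT_COLUMNS].to_csv(
        path, index=False, float_format=None, na_rep=""
    )


def read_endpoint_table(path: str | Path):
    """Read an endpoint table written by :func:`write_endpoint_table`."""
    from .endpoints import EndpointTable

    frame = _read_csv(Path(path), ENDPOINT_COLUMNS, "endpoints")
    return EndpointTable(frame)
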