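"""Abundance-ratio database: schema, validation, RR computation, summaries.

One record is a hunted/control abundance contrast for one species at one
site, plus the covariates used by the hurdle model. The response ratio is
RR = ln(X_h / X_c); contrasts with X_h = 0 are flagged as local extirpations
and feed the binomial stage instead of the Gaussian stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

__all__ = [
    "DIET_GUILDS",
    "AbundanceRecord",
    "RatioObservation",
    "ValidationError",
    "compute_response_ratio",
    "load_records",
    "write_records",
    "records_to_frame",
    "frame_to_observations",
    "summarize_database",
]

logger = logging.getLogger(__name__)

DIET_GUILDS = ("frugivore", "herbivore", "insectivore", "omnivore", "carnivore")

#: CSV column order for the record schema (documented in README).
RECORD_COLUMNS = [
    "study_id", "country_id", "species_id", "body_mass", "diet_guild",
    "abundance_hunted", "abundance_control", "distance_access", "hpd",
    "stunting", "travel_time", "livestock_biomass", "literacy", "protected",
    "year",
]


class ValidationError(ValueError):
    """A record or table failed schema validation."""


@dataclass(frozen=True)
class AbundanceRecord:
    study_id: str
    country_id: str
    species_id: str
    body_mass: float          # kg, > 0
    diet_guild: str           # one of DIET_GUILDS
    abundance_hunted: float   # X_h, >= 0
    abundance_control: float  # X_c, > 0
    distance_access: float    # km, >= 0
    hpd: float                # individuals / km^2, >= 0
    stunting: float           # proportion in [0, 1]
    travel_time: float        # minutes, >= 0
    livestock_biomass: float  # kg / km^2, >= 0
    literacy: float           # proportion in [0, 1]
    protected: bool
    year: int

    def validate(self) -> None:
        for name in ("study_id", "country_id", "species_id"):
            if not str(getattr(self, name)):
                raise ValidationError(f"{name} must be non-empty")
        if self.diet_guild not in DIET_GUILDS:
            raise ValidationError(
                f"diet_guild {self.diet_guild!r} not in {DIET_GUILDS}")
        numeric = {
            "body_mass": self.body_mass,
            "abundance_hunted": self.abundance_hunted,
            "abundance_control": self.abundance_control,
            "distance_access": self.distance_access,
            "hpd": self.hpd,
            "stunting": self.stunting,
            "travel_time": self.travel_time,
            "livestock_biomass": self.livestock_biomass,
            "literacy": self.literacy,
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValidationError(f"{name} is not finite: {value!r}")
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be > 0")
        if self.abundance_hunted < 0:
            raise ValidationError("abundance_hunted must be >= 0")
        if self.abundance_control <= 0:
            raise ValidationError(
                "abundance_control must be > 0 (ratio undefined)")
        for name in ("distance_access", "hpd", "travel_time",
                     "livestock_biomass"):
            if numeric[name] < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("stunting", "literacy"):
            if not 0.0 <= numeric[name] <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class RatioObservation:
    """A record together with its derived response: extirpation flag or RR."""

    record: AbundanceRecord
    extirpated: bool
    rr: float | None

    def __post_init__(self) -> None:
        if self.extirpated != (self.record.abundance_hunted == 0):
            raise ValidationError("extirpated flag inconsistent with X_h")
        if not self.extirpated and (self.rr is None or not math.isfinite(self.rr)):
            raise ValidationError("rr must be finite for non-extirpated records")
        if self.extirpated and self.rr is not None:
            raise ValidationError("rr must be undefined for extirpated records")


def compute_response_ratio(x_h: float, x_c: float) -> tuple[bool, float | None]:
    """Return (extirpated, rr) for one hunted/control abundance contrast.

    rr = ln(x_h / x_c), undefined (None) when x_h = 0; negative under
    decline, positive under increase.
    """
    if not math.isfinite(float(x_c)):
        raise ValidationError(f"abundance_control is not finite: {x_c!r}")
    if not math.isfinite(float(x_h)):
        raise ValidationError(f"abundance_hunted is not finite: {x_h!r}")
    if x_c <= 0:
        raise ValidationError("abundance_control must be > 0")
    if x_h < 0:
        raise ValidationError("abundance_hunted must be >= 0")
    if x_h == 0:
        return True, None
    return False, math.log(x_h / x_c)


def observe(record: AbundanceRecord) -> RatioObservation:
    extirpated, rr = compute_response_ratio(
        record.abundance_hunted, record.abundance_control)
    return RatioObservation(record=record, extirpated=extirpated, rr=rr)


def load_records(path, strict: bool = False) -> list[AbundanceRecord]:
    """Read the record CSV; invalid rows are skipped (logged) or, with
    ``strict=True``, abort the load."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    records: list[AbundanceRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = AbundanceRecord(
                study_id=str(row.study_id),
                country_id=str(row.country_id),
                species_id=str(row.species_id),
                body_mass=float(row.body_mass),
                diet_guild=str(row.diet_guild),
                abundance_hunted=float(row.abundance_hunted),
                abundance_control=float(row.abundance_control),
                distance_access=float(row.distance_access),
                hpd=float(row.hpd),
                stunting=float(row.stunting),
                travel_time=float(row.travel_time),
                livestock_biomass=float(row.livestock_biomass),
                literacy=float(row.literacy),
                protected=_parse_bool(row.protected),
                year=int(row.year),
            )
            rec.validate()
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"row {i + 2}: {exc}") from exc
            logger.warning("skipping row %d: %s", i + 2, exc)
            n_rejected += 1
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("rejected %d of %d rows", n_rejected, len(df))
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def write_records(records: list[AbundanceRecord], path) -> None:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(AbundanceRecord)}
            for r in records]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def records_to_frame(records: list[AbundanceRecord]) -> pd.DataFrame:
    """Records -> observation frame with derived ``extirpated`` / ``rr``."""
    rows = []
    for r in records:
        extirpated, rr = compute_response_ratio(
            r.abundance_hunted, r.abundance_control)
        row = {f.name: getattr(r, f.name) for f in dc_fields(AbundanceRecord)}
        row["extirpated"] = extirpated
        row["rr"] = np.nan if rr is None else rr
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + ["extirpated", "rr"])


def frame_to_observations(df: pd.DataFrame) -> list[RatioObservation]:
    out = []
    for row in df.itertuples(index=False):
        rec = AbundanceRecord(
            str(row.study_id), str(row.country_id), str(row.species_id),
            float(row.body_mass), str(row.diet_guild),
            float(row.abundance_hunted), float(row.abundance_control),
            float(row.distance_access), float(row.hpd), float(row.stunting),
            float(row.travel_time), float(row.livestock_biomass),
            float(row.literacy), _parse_bool(row.protected), int(row.year))
        out.append(observe(rec))
    return out


def summarize_database(records) -> dict[str, int]:
    """Bookkeeping counts over records (or an observation frame)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(list(records))
    if len(df) == 0:
        return {"n_records": 0, "n_zero": 0, "n_nonzero": 0, "n_studies": 0,
                "n_species": 0, "n_countries": 0}
    n_zero = int((df["abundance_hunted"] == 0).sum())
    return {
        "n_records": int(len(df)),
        "n_zero": n_zero,
        "n_nonzero": int(len(df) - n_zero),
        "n_studies": int(df["study_id"].nunique()),
        "n_species": int(df["species_id"].nunique()),
        "n_countries": int(df["country_id"].nunique()),
    }
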