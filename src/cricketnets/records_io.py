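"""Observation-record data model and CSV I/O.

The pipeline's sole input is an :class:`ObservationSet`: an adult roster,
per-individual burrow-occupancy durations, male-male fight events and
male-female mating events. All four parts are read from / written to plain
CSV with fixed, documented schemas (see :data:`SCHEMAS`).

Conventions
-----------
* Time is an integer day index from an arbitrary season origin.
* An individual's ``death_day`` is its last-observation day when death was
  not observed directly; the schema stores only the resolved value.
* Occupancy is pre-aggregated per (individual, burrow): ``duration`` is the
  total time the individual was observed at that burrow, in arbitrary
  nonnegative time units (only relative magnitudes matter downstream).
* The reader is row-order insensitive; in-memory collections are kept in a
  canonical sort order, so ``write -> read`` is the identity and writing is
  byte-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .exceptions import (
    LifespanViolationError,
    LifespanViolationWarning,
    ReferentialIntegrityError,
    SchemaError,
)

__all__ = [
    "Individual",
    "OccupancyRecord",
    "FightEvent",
    "MatingEvent",
    "ObservationSet",
    "read_observation_set",
    "write_observation_set",
    "SCHEMAS",
]

#: column order for each of the four CSV files (also the write order)
SCHEMAS = {
    "roster": ["id", "sex", "emergence_day", "death_day"],
    "occupancy": ["individual_id", "burrow_id", "duration"],
    "fights": ["day", "arriving_male_id", "resident_male_id", "burrow_id"],
    "matings": ["day", "male_id", "female_id", "spermatophore_transferred"],
}


@dataclass(frozen=True, order=True)
class Individual:
    """One adult cricket: id, sex and adult lifespan in day indices."""

    id: str
    sex: Literal["male", "female"]
    emergence_day: int
    death_day: int

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.emergence_day > self.death_day:
            raise ValueError(
                f"individual {self.id!r}: emergence_day {self.emergence_day} "
                f"> death_day {self.death_day}"
            )

    def alive_on(self, day: int) -> bool:
        return self.emergence_day <= day <= self.death_day


@dataclass(frozen=True, order=True)
class OccupancyRecord:
    """Total observed time of one individual at one burrow."""

    individual_id: str
    burrow_id: str
    duration: float

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError(
                f"negative duration for ({self.individual_id}, {self.burrow_id})"
            )


@dataclass(frozen=True, order=True)
class FightEvent:
    """A male arrived at a burrow and fought the resident male."""

    day: int
    arriving_male_id: str
    resident_male_id: str
    burrow_id: str

    def __post_init__(self):
        if self.arriving_male_id == self.resident_male_id:
            raise ValueError(f"male {self.arriving_male_id!r} cannot fight himself")


@dataclass(frozen=True, order=True)
class MatingEvent:
    """A mating; only events with ``spermatophore_transferred`` enter the
    sperm-competition analyses (filtering happens downstream, not here)."""

    day: int
    male_id: str
    female_id: str
    spermatophore_transferred: bool


@dataclass
class ObservationSet:
    """Roster plus the three event tables; canonical sort order throughout."""

    roster: list[Individual] = field(default_factory=list)
    occupancy: list[OccupancyRecord] = field(default_factory=list)
    fights: list[FightEvent] = field(default_factory=list)
    matings: list[MatingEvent] = field(default_factory=list)

    def __post_init__(self):
        self.roster = sorted(self.roster)
        self.occupancy = sorted(self.occupancy)
        self.fights = sorted(self.fights)
        self.matings = sorted(self.matings)

    # -- convenience views ------------------------------------------------
    @property
    def individuals(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.roster}

    @property
    def male_ids(self) -> list[str]:
        return [ind.id for ind in self.roster if ind.sex == "male"]

    @property
    def female_ids(self) -> list[str]:
        return [ind.id for ind in self.roster if ind.sex == "female"]

    # -- validation -------------------------------------------------------
    def validate(
        self, on_lifespan_violation: Literal["warn", "error", "ignore"] = "warn"
    ) -> list[str]:
        """Check roster uniqueness, referential integrity and lifespans.

        Returns the list of lifespan-violation messages (possibly empty).
        Referential problems always raise; lifespan problems warn by
        default and can be escalated to an error or silenced.
        """
        ids = [ind.id for ind in self.roster]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferentialIntegrityError(f"duplicate roster ids: {dupes}")
        by_id = self.individuals

        bad_rows: list[str] = []
        for k, rec in enumerate(self.occupancy):
            if rec.individual_id not in by_id:
                bad_rows.append(f"occupancy[{k}]: unknown id {rec.individual_id!r}")
        for k, ev in enumerate(self.fights):
            for role, mid in (
                ("arriving", ev.arriving_male_id),
                ("resident", ev.resident_male_id),
            ):
                ind = by_id.get(mid)
                if ind is None:
                    bad_rows.append(f"fights[{k}]: unknown {role} male {mid!r}")
                elif ind.sex != "male":
                    bad_rows.append(f"fights[{k}]: {role} id {mid!r} is not male")
        for k, ev in enumerate(self.matings):
            m, f = by_id.get(ev.male_id), by_id.get(ev.female_id)
            if m is None:
                bad_rows.append(f"matings[{k}]: unknown male {ev.male_id!r}")
            elif m.sex != "male":
                bad_rows.append(f"matings[{k}]: male_id {ev.male_id!r} is not male")
            if f is None:
                bad_rows.append(f"matings[{k}]: unknown female {ev.female_id!r}")
            elif f.sex != "female":
                bad_rows.append(f"matings[{k}]: female_id {ev.female_id!r} is not female")
        if bad_rows:
            raise ReferentialIntegrityError(
                "events reference unknown or mis-sexed individuals:\n  "
                + "\n  ".join(bad_rows)
            )

        violations: list[str] = []
        for k, ev in enumerate(self.fights):
            for mid in (ev.arriving_male_id, ev.resident_male_id):
                if not by_id[mid].alive_on(ev.day):
                    violations.append(
                        f"fights[{k}]: day {ev.day} outside lifespan of {mid!r}"
                    )
        for k, ev in enumerate(self.matings):
            for pid in (ev.male_id, ev.female_id):
                if not by_id[pid].alive_on(ev.day):
                    violations.append(
                        f"matings[{k}]: day {ev.day} outside lifespan of {pid!r}"
                    )
        if violations:
            msg = "events outside participants' adult lifespans:\n  " + "\n  ".join(
                violations
            )
            if on_lifespan_violation == "error":
                raise LifespanViolationError(msg)
            if on_lifespan_violation == "warn":
                warnings.warn(msg, LifespanViolationWarning, stacklevel=2)
        return violations

    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.roster), len(self.occupancy), len(self.fights), len(self.matings))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"cannot parse boolean value {v!r}")


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name} file {path.name!r} is missing column(s): {', '.join(missing)}"
        )
    return df


def read_observation_set(
    roster_path: str | Path,
    occupancy_path: str | Path,
    fights_path: str | Path,
    matings_path: str | Path,
    on_lifespan_violation: Literal["warn", "error", "ignore"] = "warn",
) -> ObservationSet:
    """Read and fully validate the four-CSV observation bundle."""
    roster_df = _read_table(roster_path, "roster")
    occ_df = _read_table(occupancy_path, "occupancy")
    fight_df = _read_table(fights_path, "fights")
    mate_df = _read_table(matings_path, "matings")

    roster = [
        Individual(r["id"], r["sex"], int(r["emergence_day"]), int(r["death_day"]))
        for r in roster_df.to_dict("records")
    ]
    occupancy = [
        OccupancyRecord(r["individual_id"], r["burrow_id"], float(r["duration"]))
        for r in occ_df.to_dict("records")
    ]
    fights = [
        FightEvent(int(r["day"]), r["arriving_male_id"], r["resident_male_id"], r["burrow_id"])
        for r in fight_df.to_dict("records")
    ]
    matings = [
        MatingEvent(
            int(r["day"]), r["male_id"], r["female_id"],
            _parse_bool(r["spermatophore_transferred"]),
        )
        for r in mate_df.to_dict("records")
    ]
    obs = ObservationSet(roster, occupancy, fights, matings)
    obs.validate(on_lifespan_violation=on_lifespan_violation)
    return obs


def read_observation_dir(
    directory: str | Path,
    on_lifespan_violation: Literal["warn", "error", "ignore"] = "warn",
) -> ObservationSet:
    """Read a bundle written by :func:`write_observation_set`."""
    d = Path(directory)
    return read_observation_set(
        d / "roster.csv", d / "occupancy.csv", d / "fights.csv", d / "matings.csv",
        on_lifespan_violation=on_lifespan_violation,
    )


def write_observation_set(obs: ObservationSet, directory: str | Path) -> dict[str, Path]:
    """Write the four CSVs (sorted rows, fixed column order; byte-stable).

    Returns a mapping from table name to the written path.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {name: d / f"{name}.csv" for name in SCHEMAS}

    def dump(rows: Iterable[dict], name: str):
        df = pd.DataFrame(list(rows), columns=SCHEMAS[name])
        df.to_csv(paths[name], index=False, lineterminator="\n")

    dump(
        (
            {"id": i.id, "sex": i.sex, "emergence_day": i.emergence_day,
             "death_day": i.death_day}
            for i in obs.roster
        ),
        "roster",
    )
    dump(
        (
            {"individual_id": r.individual_id, "burrow_id": r.burrow_id,
             "duration": r.duration}
            for r in obs.occupancy
        ),
        "occupancy",
    )
    dump(
        (
            {"day": e.day, "arriving_male_id": e.arriving_male_id,
             "resident_male_id": e.resident_male_id, "burrow_id": e.burrow_id}
            for e in obs.fights
        ),
        "fights",
    )
    dump(
        (
            {"day": e.day, "male_id": e.male_id, "female_id": e.female_id,
             "spermatophore_transferred": e.spermatophore_transferred}
            for e in obs.matings
        ),
        "matings",
    )
    return paths
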