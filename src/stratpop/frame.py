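"""Sampling-frame data model and delimited-text I/O.

The frame has two levels.  *Sections* are named neighbourhoods of a city,
each carrying aggregate counts (residential structures, households,
persons).  *Residences* are the primary sampling units: one record per
residential structure with its occupant count.  The packaged fixture is
the 20-section survey of Bo City, Sierra Leone (1,979 residential
structures, 25,954 persons); the residence-level survey file was never
released, so residence records are either user-supplied or synthesised
(:mod:`stratpop.synthetic`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reserved source name for the packaged Bo City section table.
BO_FIXTURE = "bo2011"

SECTION_COLUMNS = [
    "section",
    "area_km2",
    "n_residential",
    "n_structures_total",
    "n_households",
    "n_persons",
    "mean_occupancy",
]

RESIDENCE_COLUMNS = ["section", "persons", "households"]


class FrameValidationError(ValueError):
    """A table row violates a frame invariant; message names row and field."""


@dataclass(frozen=True)
class SectionRecord:
    """One section (cluster) of the survey frame.

    ``mean_occupancy`` is persons per residential structure; it is
    recomputed on load and compared with the stored value at two decimals.
    """

    name: str
    area_km2: float
    n_residential: int
    n_structures_total: int
    n_households: int
    n_persons: int
    mean_occupancy: float

    def __post_init__(self) -> None:
        if self.n_residential < 1:
            raise FrameValidationError(
                f"section {self.name!r}: n_residential must be >= 1, "
                f"got {self.n_residential}"
            )
        if self.n_persons < self.n_residential:
            raise FrameValidationError(
                f"section {self.name!r}: n_persons ({self.n_persons}) is below "
                f"n_residential ({self.n_residential}); every residence houses "
                "at least one person"
            )
        recomputed = self.n_persons / self.n_residential
        if abs(round(recomputed, 2) - round(self.mean_occupancy, 2)) > 0.011:
            warnings.warn(
                f"section {self.name!r}: stored mean_occupancy "
                f"{self.mean_occupancy} differs from recomputed "
                f"{recomputed:.2f}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ResidenceRecord:
    """One residential structure (primary sampling unit)."""

    section: str
    persons: int
    households: int = 1

    def __post_init__(self) -> None:
        if int(self.persons) != self.persons or self.persons < 1:
            raise FrameValidationError(
                f"residence in section {self.section!r}: persons must be an "
                f"integer >= 1, got {self.persons}"
            )
        if self.households < 1:
            raise FrameValidationError(
                f"residence in section {self.section!r}: households must be "
                f">= 1, got {self.households}"
            )


@dataclass
class SurveyFrame:
    """Sections plus (optionally) the residence-level records they summarise."""

    sections: list[SectionRecord]
    residences: list[ResidenceRecord] | None = None
    provenance: str = "file"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FrameValidationError(f"duplicate section names: {dupes}")
        if self.residences is not None:
            known = set(names)
            for r in self.residences:
                if r.section not in known:
                    raise FrameValidationError(
                        f"residence references unknown section {r.section!r}"
                    )

    # -- aggregate views -------------------------------------------------

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def total_residences(self) -> int:
        return sum(s.n_residential for s in self.sections)

    @property
    def total_persons(self) -> int:
        return sum(s.n_persons for s in self.sections)

    def section_values(self, variable: str) -> np.ndarray:
        """Section-level stratification variable, in section order.

        ``variable`` is ``"structures"`` (residential structures per
        section) or ``"persons"`` (total persons per section).
        """
        if variable == "structures":
            return np.array([s.n_residential for s in self.sections], float)
        if variable == "persons":
            return np.array([s.n_persons for s in self.sections], float)
        raise ValueError(f"unknown section variable {variable!r}")

    def occupancies(self) -> np.ndarray:
        """Persons per residence for every residence record, in order."""
        if self.residences is None:
            raise ValueError("frame carries no residence-level records")
        return np.array([r.persons for r in self.residences], float)

    def residence_sections(self) -> list[str]:
        if self.residences is None:
            raise ValueError("frame carries no residence-level records")
        return [r.section for r in self.residences]


@dataclass(frozen=True)
class MarginRow:
    section: str
    expected_residences: int
    observed_residences: int
    expected_persons: int
    observed_persons: int

    @property
    def ok(self) -> bool:
        return (
            self.expected_residences == self.observed_residences
            and self.expected_persons == self.observed_persons
        )


@dataclass(frozen=True)
class MarginReport:
    rows: tuple[MarginRow, ...]

    @property
    def all_pass(self) -> bool:
        return all(r.ok for r in self.rows)

    @property
    def flagged(self) -> tuple[MarginRow, ...]:
        return tuple(r for r in self.rows if not r.ok)


def _read_csv(source: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FrameValidationError(
            f"{source}: missing required column(s) {missing}"
        )
    return df


def load_section_table(source: str | Path = BO_FIXTURE) -> list[SectionRecord]:
    """Read a section table from CSV, or the packaged Bo City fixture.

    Pass :data:`BO_FIXTURE` (the default) for the packaged 20-section
    table; otherwise ``source`` is a path to a CSV with the columns
    ``section,area_km2,n_residential,n_structures_total,n_households,
    n_persons,mean_occupancy``.
    """
    if source == BO_FIXTURE:
        with resources.files("stratpop.data").joinpath("bo_sections.csv").open() as fh:
            df = _read_csv(fh, SECTION_COLUMNS)
    else:
        df = _read_csv(source, SECTION_COLUMNS)

    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = str(row["section"])
        if name in seen:
            raise FrameValidationError(f"row {i}: duplicate section name {name!r}")
        seen.add(name)
        for col in SECTION_COLUMNS[1:]:
            if not np.isfinite(pd.to_numeric(row[col], errors="coerce")):
                raise FrameValidationError(
                    f"row {i} ({name!r}): non-numeric value in field {col!r}"
                )
        try:
            records.append(
                SectionRecord(
                    name=name,
                    area_km2=float(row["area_km2"]),
                    n_residential=int(row["n_residential"]),
                    n_structures_total=int(row["n_structures_total"]),
                    n_households=int(row["n_households"]),
                    n_persons=int(row["n_persons"]),
                    mean_occupancy=float(row["mean_occupancy"]),
                )
            )
        except FrameValidationError as exc:
            raise FrameValidationError(f"row {i}: {exc}") from None
    return records


def load_residence_table(
    source: str | Path,
    sections: Iterable[SectionRecord] | None = None,
) -> list[ResidenceRecord]:
    """Read residence-level records (``section,persons,households`` CSV).

    When ``sections`` is supplied, every residence must name a known
    section.  An empty file yields an empty list with a warning.
    """
    df = _read_csv(source, RESIDENCE_COLUMNS)
    if df.empty:
        warnings.warn(f"{source}: residence table is empty", stacklevel=2)
        return []
    known = {s.name for s in sections} if sections is not None else None
    records = []
    for i, row in df.iterrows():
        persons = pd.to_numeric(row["persons"], errors="coerce")
        if not np.isfinite(persons) or persons != int(persons) or persons < 1:
            raise FrameValidationError(
                f"row {i}: persons must be an integer >= 1, got {row['persons']!r}"
            )
        name = str(row["section"])
        if known is not None and name not in known:
            raise FrameValidationError(f"row {i}: unknown section {name!r}")
        records.append(
            ResidenceRecord(
                section=name,
                persons=int(persons),
                households=int(row["households"]),
            )
        )
    return records


def write_section_table(sections: Iterable[SectionRecord], path: str | Path) -> None:
    rows = [
        {
            "section": s.name,
            "area_km2": s.area_km2,
            "n_residential": s.n_residential,
            "n_structures_total": s.n_structures_total,
            "n_households": s.n_households,
            "n_persons": s.n_persons,
            "mean_occupancy": s.mean_occupancy,
        }
        for s in sections
    ]
    pd.DataFrame(rows)[SECTION_COLUMNS].to_csv(path, index=False)


def write_residence_table(
    residences: Iterable[ResidenceRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"section": r.section, "persons": r.persons, "households": r.households}
            for r in residences
        ]
    ).to_csv(path, index=False)


def check_margins(frame: SurveyFrame) -> MarginReport:
    """Compare residence-level counts and person sums against section totals."""
    if frame.residences is None:
        raise ValueError("margin check requires residence-level records")
    counts: dict[str, int] = {s.name: 0 for s in frame.sections}
    sums: dict[str, int] = {s.name: 0 for s in frame.sections}
    for r in frame.residences:
        counts[r.section] += 1
        sums[r.section] += r.persons
    rows = tuple(
        MarginRow(
            section=s.name,
            expected_residences=s.n_residential,
            observed_residences=counts[s.name],
            expected_persons=s.n_persons,
            observed_persons=sums[s.name],
        )
        for s in frame.sections
    )
    return MarginReport(rows=rows)
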