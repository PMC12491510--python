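"""Containers and I/O for two-test, multi-population diagnostic study data.

In a Hui-Walter design the observed data are, for each population, the 2x2
cross-classification of two binary test results.  Cells are indexed
``(test1, test2)`` with ``1`` meaning a positive result, so ``n10`` counts
individuals positive on the first test and negative on the second.  The
study design this package emulates pairs a clinician-completed burnout
instrument (EDTB, hetero-assessment) with the self-reported Oldenburg
Burnout Inventory (OLBI), whose total score ranges from 16 to 64 and is
dichotomized at the high-severity cut-off: scores strictly greater than 44
count as positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OLBI_MIN_SCORE",
    "OLBI_MAX_SCORE",
    "OLBI_CUTOFF",
    "CELL_COLUMNS",
    "PopulationCounts",
    "StudyData",
    "IndividualRecord",
    "dichotomize_olbi",
    "tabulate",
    "read_counts",
    "write_counts",
    "read_individuals",
    "write_individuals",
]

OLBI_MIN_SCORE = 16
OLBI_MAX_SCORE = 64
OLBI_CUTOFF = 44

#: Cell order used throughout: (test1, test2) outcomes (1,1), (1,0), (0,1), (0,0).
CELL_COLUMNS = ("n11", "n10", "n01", "n00")


def dichotomize_olbi(score: int) -> int:
    """Dichotomize an OLBI total score at the high-severity cut-off.

    Scores strictly greater than 44 are positive; 44 itself is negative.

    Parameters
    ----------
    score
        OLBI total, an integer between 16 and 64 (16 items scored 1-4).

    Returns
    -------
    int
        1 for a positive (high-severity) result, 0 otherwise.
    """
    score = int(score)
    if not OLBI_MIN_SCORE <= score <= OLBI_MAX_SCORE:
        raise ValueError(
            f"OLBI score {score} outside the admissible range "
            f"[{OLBI_MIN_SCORE}, {OLBI_MAX_SCORE}]"
        )
    return int(score > OLBI_CUTOFF)


def _check_binary(value, name: str) -> int:
    value = int(value)
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value}")
    return value


@dataclass(frozen=True)
class PopulationCounts:
    """Cross-classified test results for one population.

    ``n11`` counts individuals positive on both tests, ``n10`` positive on
    test 1 only, ``n01`` positive on test 2 only, ``n00`` negative on both.
    """

    population_id: str
    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in CELL_COLUMNS:
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(
                    f"count {name}={value!r} for population "
                    f"{self.population_id!r} must be a non-negative integer"
                )
            object.__setattr__(self, name, int(value))
        if self.total < 1:
            raise ValueError(
                f"population {self.population_id!r} has no observations"
            )

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        """Counts in cell order (1,1), (1,0), (0,1), (0,0)."""
        return np.array([self.n11, self.n10, self.n01, self.n00], dtype=np.int64)


@dataclass(frozen=True)
class StudyData:
    """Observed counts for every population plus the two test labels."""

    populations: tuple[PopulationCounts, ...]
    test_names: tuple[str, str] = ("EDTB", "OLBI")

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "test_names", tuple(self.test_names))
        if len(self.populations) < 1:
            raise ValueError("StudyData requires at least one population")
        if len(self.test_names) != 2:
            raise ValueError("exactly two tests are modeled")
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"population ids are not unique: {ids}")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def population_ids(self) -> tuple[str, ...]:
        return tuple(p.population_id for p in self.populations)

    @property
    def totals(self) -> np.ndarray:
        return np.array([p.total for p in self.populations], dtype=np.int64)

    def counts_matrix(self) -> np.ndarray:
        """Counts as an (n_populations, 4) array in cell order."""
        return np.stack([p.as_array() for p in self.populations])


@dataclass(frozen=True)
class IndividualRecord:
    """One study participant: population label and both test outcomes.

    The second test result may be given directly or derived from an OLBI
    total score; when both are present they must agree.
    """

    population_id: str
    test1_result: int
    olbi_score: int | None = None
    test2_result: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "test1_result", _check_binary(self.test1_result, "test1_result")
        )
        if self.olbi_score is not None:
            derived = dichotomize_olbi(self.olbi_score)
            if self.test2_result is not None and int(self.test2_result) != derived:
                raise ValueError(
                    f"test2_result={self.test2_result} contradicts "
                    f"olbi_score={self.olbi_score} for population "
                    f"{self.population_id!r}"
                )
            object.__setattr__(self, "olbi_score", int(self.olbi_score))
            object.__setattr__(self, "test2_result", derived)
        elif self.test2_result is not None:
            object.__setattr__(
                self, "test2_result", _check_binary(self.test2_result, "test2_result")
            )

    def resolved_test2(self) -> int:
        if self.test2_result is None:
            raise ValueError(
                f"record in population {self.population_id!r} has neither an "
                "olbi_score nor a test2_result"
            )
        return self.test2_result


def tabulate(
    records: Sequence[IndividualRecord],
    test_names: tuple[str, str] = ("EDTB", "OLBI"),
) -> StudyData:
    """Cross-tabulate individual records into per-population 2x2 counts.

    Populations appear in the output in order of first appearance in
    ``records``; per-population cell totals equal the number of records.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to tabulate")
    order: list[str] = []
    cells: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        if rec.test2_result is None:
            raise ValueError(
                f"record #{i} (population {rec.population_id!r}) has neither "
                "an olbi_score nor a test2_result"
            )
        pid = rec.population_id
        if pid not in cells:
            order.append(pid)
            cells[pid] = [0, 0, 0, 0]
        idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[
            (rec.test1_result, rec.test2_result)
        ]
        cells[pid][idx] += 1
    pops = tuple(
        PopulationCounts(pid, *cells[pid]) for pid in order
    )
    return StudyData(populations=pops, test_names=test_names)


# ---------------------------------------------------------------------------
# File I/O.  CSV files carry a header comment documenting the cell
# convention; JSON mirrors the same structure explicitly.
# ---------------------------------------------------------------------------

_COUNTS_HEADER = (
    "# cells indexed (test1, test2), 1 = positive: "
    "n11, n10, n01, n00\n"
)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    return "csv"


def write_counts(data: StudyData, path, fmt: str | None = None) -> None:
    """Write cross-tabulated counts to CSV or JSON (inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        payload = {
            "test_names": list(data.test_names),
            "populations": [
                {
                    "population_id": p.population_id,
                    **{c: getattr(p, c) for c in CELL_COLUMNS},
                }
                for p in data.populations
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    with open(path, "w", newline="") as fh:
        fh.write(f"# tests: {data.test_names[0]},{data.test_names[1]}\n")
        fh.write(_COUNTS_HEADER)
        fh.write("population," + ",".join(CELL_COLUMNS) + "\n")
        for p in data.populations:
            fh.write(
                f"{p.population_id},{p.n11},{p.n10},{p.n01},{p.n00}\n"
            )


def read_counts(path, fmt: str | None = None) -> StudyData:
    """Read cross-tabulated counts from CSV or JSON.

    CSV requires columns ``population, n11, n10, n01, n00``; a leading
    ``# tests: A,B`` comment (as written by :func:`write_counts`) restores
    the test labels.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        payload = json.loads(path.read_text())
        test_names = tuple(payload.get("test_names", ("EDTB", "OLBI")))
        rows = payload["populations"]
        pops = tuple(
            PopulationCounts(
                str(r["population_id"]),
                *[_require_cell(r, c) for c in CELL_COLUMNS],
            )
            for r in rows
        )
        return StudyData(populations=pops, test_names=test_names)

    test_names: tuple[str, str] = ("EDTB", "OLBI")
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# tests:"):
                parts = line.removeprefix("# tests:").strip().split(",")
                if len(parts) == 2:
                    test_names = (parts[0].strip(), parts[1].strip())
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in ("population", *CELL_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"counts file {path} is missing column(s): {missing}")
    pops = tuple(
        PopulationCounts(
            str(row["population"]),
            int(row["n11"]),
            int(row["n10"]),
            int(row["n01"]),
            int(row["n00"]),
        )
        for _, row in frame.iterrows()
    )
    return StudyData(populations=pops, test_names=test_names)


def _require_cell(row: dict, column: str) -> int:
    if column not in row:
        raise ValueError(f"population entry is missing column {column!r}")
    return int(row[column])


def write_individuals(records: Sequence[IndividualRecord], path, fmt: str | None = None) -> None:
    """Write individual-level records to CSV or JSON."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows = [
        {
            "population": r.population_id,
            "edtb": r.test1_result,
            "olbi_score": r.olbi_score if r.olbi_score is not None else "",
            "olbi": r.test2_result if r.test2_result is not None else "",
        }
        for r in records
    ]
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
        return
    pd.DataFrame(rows).to_csv(path, index=False)


def read_individuals(path, fmt: str | None = None) -> list[IndividualRecord]:
    """Read individual-level records from CSV or JSON."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        rows = json.loads(path.read_text())
    else:
        frame = pd.read_csv(path)
        if "population" not in frame.columns or "edtb" not in frame.columns:
            raise ValueError(
                f"individuals file {path} requires columns 'population' and 'edtb'"
            )
        rows = frame.to_dict(orient="records")
    records = []
    for r in rows:
        score = r.get("olbi_score")
        if score in ("", None) or (isinstance(score, float) and np.isnan(score)):
            score = None
        olbi = r.get("olbi")
        if olbi in ("", None) or (isinstance(olbi, float) and np.isnan(olbi)):
            olbi = None
        records.append(
            IndividualRecord(
                population_id=str(r["population"]),
                test1_result=int(r["edtb"]),
                olbi_score=None if score is None else int(score),
                test2_result=None if olbi is None else int(olbi),
            )
        )
    return records
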