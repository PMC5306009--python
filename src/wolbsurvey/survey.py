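"""Screening-survey tables: load, validate, summarize, reduce and filter.

The central object is :class:`SurveyTable`, a thin wrapper around a pandas
DataFrame holding one row per (species, study sample): taxonomic order and
family, larval habitat (aquatic or terrestrial), the number of individuals
screened for *Wolbachia* and the number that tested positive.

Two database variants matter downstream: the *full* table (all rows) and the
*reduced* table, which keeps for every species only the sample with the most
individuals tested — a guard against targeted resampling of species already
known to be infected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

log = logging.getLogger("wolbsurvey")

HABITATS = ("aquatic", "terrestrial")

#: Canonical column order of the native delimited format.
COLUMNS = ["species_id", "order", "family", "habitat", "n_tested", "n_infected", "source"]

#: Columns that must be present (family and source may be empty).
REQUIRED_COLUMNS = ["species_id", "order", "habitat", "n_tested", "n_infected"]


class SurveyFormatError(ValueError):
    """A file could not be mapped onto the screening-record schema."""


class SurveyValidationError(ValueError):
    """One or more rows violate the screening-record invariants.

    Attributes
    ----------
    problems : list of (row_number, message) tuples; row numbers are 1-based
        positions in the source (header excluded).
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.problems[:20])
        more = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class ScreeningRecord:
    """One screening sample of one species (or morphospecies)."""

    species_id: str
    order: str
    family: str
    habitat: str
    n_tested: int
    n_infected: int
    source: str = ""


def _validate_frame(df: pd.DataFrame) -> list[tuple[int, str]]:
    problems: list[tuple[int, str]] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        if row.habitat not in HABITATS:
            problems.append((pos, f"habitat {row.habitat!r} not in {HABITATS}"))
        if row.n_tested < 1:
            problems.append((pos, f"n_tested={row.n_tested} < 1"))
        if row.n_infected < 0:
            problems.append((pos, f"n_infected={row.n_infected} < 0"))
        elif row.n_infected > row.n_tested:
            problems.append(
                (pos, f"n_infected={row.n_infected} > n_tested={row.n_tested}")
            )
        if not str(row.species_id):
            problems.append((pos, "empty species_id"))
    return problems


class SurveyTable:
    """Ordered collection of screening records plus free-form metadata.

    Parameters
    ----------
    frame
        DataFrame with the canonical columns (:data:`COLUMNS`); extra columns
        are dropped, missing family/source filled with "".
    metadata
        Free-form notes (database name, reduction applied, source path).
    validate
        Check the record invariants (0 <= n_infected <= n_tested, n_tested >= 1,
        habitat in {aquatic, terrestrial}); raise SurveyValidationError listing
        offending rows.
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None, *,
                 validate: bool = True):
        df = frame.copy()
        for col in ("family", "source"):
            if col not in df.columns:
                df[col] = ""
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SurveyFormatError(f"missing required column(s): {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        for col in ("species_id", "order", "family", "habitat", "source"):
            df[col] = df[col].fillna("").astype(str)
        try:
            df["n_tested"] = df["n_tested"].astype(np.int64)
            df["n_infected"] = df["n_infected"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise SurveyValidationError([(0, f"non-integer count column: {exc}")])
        if validate:
            problems = _validate_frame(df)
            if problems:
                raise SurveyValidationError(problems)
        self.frame = df
        self.metadata = dict(metadata or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[ScreeningRecord]:
        for row in self.frame.itertuples(index=False):
            yield ScreeningRecord(*row)

    def __eq__(self, other) -> bool:
        return isinstance(other, SurveyTable) and self.frame.equals(other.frame)

    @property
    def records(self) -> list[ScreeningRecord]:
        return list(self)

    @classmethod
    def from_records(cls, records: list[ScreeningRecord] | list[dict],
                     metadata: dict | None = None) -> "SurveyTable":
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in records]
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df, metadata)

    def checksum(self) -> str:
        """SHA-256 of the canonical CSV serialization (used by run manifests)."""
        buf = io.StringIO()
        self.frame.to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()


# -- I/O ---------------------------------------------------------------------

def read_column_map(path: str | Path) -> dict[str, str]:
    """Parse a key=value config mapping canonical field -> file header."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SurveyFormatError(f"bad column-map line (expected key=value): {line!r}")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    return mapping


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_survey(path: str | Path, column_map: dict[str, str] | str | Path | None = None,
                ) -> SurveyTable:
    """Read a delimited screening database (comma or tab, auto-detected).

    ``column_map`` maps canonical field names to the file's header names, so
    arbitrary deposited layouts can be adapted; it may be a dict or the path of
    a key=value config file.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, dtype={"species_id": str})
    if column_map is not None:
        if not isinstance(column_map, dict):
            column_map = read_column_map(column_map)
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(
            f"{path}: missing required column(s) {missing}; present: {list(df.columns)}"
        )
    table = SurveyTable(df, metadata={"source_path": str(path)})
    return table


def write_survey(table: SurveyTable, path: str | Path, sep: str = ",") -> None:
    """Write the native delimited format (canonical columns, header row)."""
    table.frame.to_csv(path, index=False, sep=sep)


# -- summaries ----------------------------------------------------------------

@dataclass
class SurveySummary:
    """Counts and shares describing a screening database."""

    n_samples: int
    n_species: int
    n_species_by_habitat: dict[str, int] = field(default_factory=dict)
    n_samples_by_habitat: dict[str, int] = field(default_factory=dict)
    n_samples_by_order: dict[str, int] = field(default_factory=dict)
    _frame: pd.DataFrame | None = None

    def share_of_family(self, family: str, habitat: str | None = None,
                        basis: str = "samples") -> float:
        """Fraction of samples (rows) or individuals attributable to a family.

        Both bases are exposed because "share of samples" can be read as rows
        or as screened individuals; rows is the default reading.
        """
        if self._frame is None or len(self._frame) == 0:
            return 0.0
        df = self._frame
        if habitat is not None:
            df = df[df["habitat"] == habitat]
        if len(df) == 0:
            return 0.0
        in_family = df["family"] == family
        if basis == "samples":
            return float(in_family.sum() / len(df))
        if basis == "individuals":
            total = df["n_tested"].sum()
            return float(df.loc[in_family, "n_tested"].sum() / total) if total else 0.0
        raise ValueError(f"basis must be 'samples' or 'individuals', got {basis!r}")


def summarize_survey(table: SurveyTable) -> SurveySummary:
    df = table.frame
    if len(df) == 0:
        return SurveySummary(0, 0, {}, {}, {}, df)
    return SurveySummary(
        n_samples=len(df),
        n_species=int(df["species_id"].nunique()),
        n_species_by_habitat={
            h: int(g["species_id"].nunique()) for h, g in df.groupby("habitat")
        },
        n_samples_by_habitat={h: int(len(g)) for h, g in df.groupby("habitat")},
        n_samples_by_order={o: int(len(g)) for o, g in df.groupby("order")},
        _frame=df,
    )


# -- reductions and filters ----------------------------------------------------

def reduce_one_per_species(table: SurveyTable) -> SurveyTable:
    """Keep one record per species: the one with the most individuals tested.

    Ties on n_tested keep the larger n_infected; remaining ties keep the first
    record in file order. Output preserves the original relative row order.
    Idempotent.
    """
    df = table.frame
    if len(df) == 0:
        meta = dict(table.metadata, reduced=True, reduction="max_n_tested")
        return SurveyTable(df, meta)
    # lexicographic argmax per species: (n_tested, n_infected, earliest position)
    order_key = df.assign(_pos=np.arange(len(df))).sort_values(
        ["n_tested", "n_infected", "_pos"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    keep_idx = order_key.drop_duplicates("species_id", keep="first").index
    out = df.loc[sorted(keep_idx)].reset_index(drop=True)
    meta = dict(table.metadata, reduced=True, reduction="max_n_tested")
    return SurveyTable(out, meta)


def exclude_family(table: SurveyTable, family: str) -> SurveyTable:
    """Drop every record of the given family (e.g. Culicidae), keeping order."""
    df = table.frame
    if family not in set(df["family"]):
        log.warning("exclude_family: family %r not present in table", family)
        return SurveyTable(df, dict(table.metadata))
    out = df[df["family"] != family].reset_index(drop=True)
    meta = dict(table.metadata)
    excluded = list(meta.get("excluded_families", []))
    excluded.append(family)
    meta["excluded_families"] = excluded
    return SurveyTable(out, meta)


def subset(table: SurveyTable, habitat: str | None = None,
           order: str | None = None) -> SurveyTable:
    """Records matching all provided predicates, original order preserved."""
    df = table.frame
    mask = pd.Series(True, index=df.index)
    meta = dict(table.metadata)
    if habitat is not None:
        mask &= df["habitat"] == habitat
        meta["habitat"] = habitat
    if order is not None:
        mask &= df["order"] == order
        meta["order"] = order
    return SurveyTable(df[mask].reset_index(drop=True), meta)
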