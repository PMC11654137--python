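"""Data model and CSV interfaces for the birth-travel pipeline.

The pipeline is built around four tables:

* a birth registry (one row per live birth, with the mother's residence
  municipality, the municipality where the birth occurred, the calendar
  year and a set of clinical / social indicator flags);
* a long-format inter-municipal distance matrix in kilometres;
* a municipality -> state / health-region lookup;
* a table of municipal socioeconomic covariates (census indicators).

Municipality codes are opaque fixed-width strings. No arithmetic is ever
performed on them; real Brazilian registries use 6-digit IBGE codes where
leading zeros are meaningful, and treating codes as integers silently
corrupts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The eight individual characteristic / risk-factor flags carried by a
#: birth record.  Each is boolean and may be missing for a given record.
FLAG_COLUMNS: tuple[str, ...] = (
    "apgar5_lt8",
    "multiple_pregnancy",
    "low_birth_weight",
    "preterm_lt37w",
    "any_pregnancy_risk",
    "edu_highschool_plus",
    "cesarean",
    "prenatal_7plus",
)

#: Required non-flag columns of a birth registry table.
BIRTH_CORE_COLUMNS: tuple[str, ...] = ("birth_id", "year", "residence_muni", "birth_muni")

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


class DistanceMissError(KeyError):
    """Lookup of an origin-destination pair absent from the distance matrix.

    A miss is a detectable condition, never silently 0: imputing zero for an
    unknown pair would deflate every distance statistic downstream.
    """


@dataclass
class BirthsSchema:
    """Column-name mapping for a birth-registry CSV.

    Defaults match the names this package writes; override any field to read
    files produced elsewhere.
    """

    birth_id: str = "birth_id"
    year: str = "year"
    residence_muni: str = "residence_muni"
    birth_muni: str = "birth_muni"
    flags: tuple[str, ...] = FLAG_COLUMNS

    def required(self) -> list[str]:
        return [self.birth_id, self.year, self.residence_muni, self.birth_muni]


@dataclass
class ValidationReport:
    """Row accounting for one reader invocation.

    Invariant: ``n_raw == n_kept + dropped_missing_residence +
    dropped_missing_destination + dropped_bad_year`` — every raw row is
    either kept or attributed to exactly one drop counter.
    """

    n_raw: int = 0
    n_kept: int = 0
    dropped_missing_residence: int = 0
    dropped_missing_destination: int = 0
    dropped_bad_year: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.dropped_missing_residence
            + self.dropped_missing_destination
            + self.dropped_bad_year
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_flag(series: pd.Series) -> pd.Series:
    """Parse a raw flag column to nullable boolean with explicit missing."""
    s = series.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[s.isin(_TRUE_TOKENS)] = True
    out[s.isin(_FALSE_TOKENS)] = False
    return out


def read_births(
    path: str | Path,
    schema: BirthsSchema | None = None,
    year_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a birth-registry CSV.

    Rows whose residence or birth municipality is missing/blank are dropped
    and counted; flag columns are parsed into a nullable boolean dtype so
    "unknown" is an explicit state distinct from False. Records with a
    missing flag are excluded only from analyses that use that flag, never
    globally, so they are retained here.

    Returns the registry as a DataFrame (columns ``birth_id, year,
    residence_muni, birth_muni`` plus any flag columns present in the file)
    together with a :class:`ValidationReport`.
    """
    schema = schema or BirthsSchema()
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:  # unreadable / malformed
        raise SchemaError(f"cannot read births file {path}: {exc}") from exc

    missing_cols = [c for c in schema.required() if c not in raw.columns]
    if missing_cols:
        raise SchemaError(
            f"births file {path} is missing required columns {missing_cols}; "
            f"found {list(raw.columns)}"
        )

    report = ValidationReport(n_raw=len(raw))

    df = pd.DataFrame(
        {
            "birth_id": raw[schema.birth_id].astype("string"),
            "year": pd.to_numeric(raw[schema.year], errors="coerce"),
            "residence_muni": raw[schema.residence_muni].astype("string").str.strip(),
            "birth_muni": raw[schema.birth_muni].astype("string").str.strip(),
        }
    )
    for flag in schema.flags:
        if flag in raw.columns:
            df[flag] = _parse_flag(raw[flag])

    bad_res = df["residence_muni"].isna() | (df["residence_muni"] == "")
    report.dropped_missing_residence = int(bad_res.sum())
    df = df[~bad_res]

    bad_dst = df["birth_muni"].isna() | (df["birth_muni"] == "")
    report.dropped_missing_destination = int(bad_dst.sum())
    df = df[~bad_dst]

    bad_year = df["year"].isna()
    if year_range is not None:
        lo, hi = year_range
        bad_year |= (df["year"] < lo) | (df["year"] > hi)
    report.dropped_bad_year = int(bad_year.sum())
    df = df[~bad_year]

    df = df.assign(year=df["year"].astype(int)).reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


def write_births(births: pd.DataFrame, path: str | Path) -> None:
    """Write a birth registry to CSV (flags as 1/0, missing left blank)."""
    out = births.copy()
    for flag in FLAG_COLUMNS:
        if flag in out.columns:
            out[flag] = out[flag].map({True: "1", False: "0"}, na_action="ignore")
    out.to_csv(path, index=False)


class DistanceMatrix:
    """Origin-destination kilometre lookup.

    Stored asymmetric, exactly as given: d(A,B) and d(B,A) are independent
    entries (road networks are not symmetric). The diagonal d(i,i) is 0 by
    construction. Lookups of absent pairs raise :class:`DistanceMissError`.
    """

    def __init__(self, frame: pd.DataFrame, n_synthesized_diagonal: int = 0):
        if list(frame.columns[:3]) != ["origin", "destination", "km"]:
            frame = frame.rename(
                columns=dict(zip(frame.columns[:3], ["origin", "destination", "km"]))
            )
        self._frame = frame[["origin", "destination", "km"]].reset_index(drop=True)
        self._lookup = self._frame.set_index(["origin", "destination"])["km"]
        if self._lookup.index.has_duplicates:
            dups = self._lookup.index[self._lookup.index.duplicated()].tolist()
            raise ValueError(f"duplicate origin-destination pairs: {dups[:10]}")
        self.n_synthesized_diagonal = n_synthesized_diagonal

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_entries(cls, entries: Mapping[tuple[str, str], float]) -> "DistanceMatrix":
        frame = pd.DataFrame(
            [(o, d, km) for (o, d), km in entries.items()],
            columns=["origin", "destination", "km"],
        )
        return cls(frame)

    @classmethod
    def from_square(cls, codes: Iterable[str], matrix: np.ndarray) -> "DistanceMatrix":
        """Build from a dense square array indexed by ``codes``."""
        codes = list(codes)
        n = len(codes)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (n, n):
            raise ValueError(f"matrix shape {matrix.shape} != ({n}, {n})")
        oi, di = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        frame = pd.DataFrame(
            {
                "origin": np.asarray(codes, dtype=object)[oi.ravel()],
                "destination": np.asarray(codes, dtype=object)[di.ravel()],
                "km": matrix.ravel(),
            }
        )
        return cls(frame)

    # -- access ------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """Long-format view (origin, destination, km) for merges."""
        return self._frame

    def km(self, origin: str, destination: str) -> float:
        try:
            return float(self._lookup.at[(origin, destination)])
        except KeyError:
            raise DistanceMissError((origin, destination)) from None

    def get(self, origin: str, destination: str, default=None):
        try:
            return self.km(origin, destination)
        except DistanceMissError:
            return default

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._lookup.index

    def __len__(self) -> int:
        return len(self._frame)

    def origins(self) -> list[str]:
        return sorted(set(self._frame["origin"]))

    def write(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a long-format distance CSV (origin, destination, km).

    Validation is strict: duplicate pairs and negative or non-zero diagonal
    distances are fatal. Diagonal entries absent from the file are
    synthesized as 0 km and counted on the returned object
    (``n_synthesized_diagonal``).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={0: str, 1: str})
    if raw.shape[1] < 3:
        raise SchemaError(
            f"distance file {path} needs columns (origin, destination, km); "
            f"found {list(raw.columns)}"
        )
    raw = raw.rename(columns=dict(zip(raw.columns[:3], ["origin", "destination", "km"])))
    raw["km"] = pd.to_numeric(raw["km"], errors="raise")

    if (raw["km"] < 0).any():
        bad = raw.loc[raw["km"] < 0].head(5)
        raise ValueError(f"negative distances:\n{bad}")
    diag = raw["origin"] == raw["destination"]
    if (raw.loc[diag, "km"] != 0).any():
        bad = raw.loc[diag & (raw["km"] != 0)].head(5)
        raise ValueError(f"non-zero diagonal distances:\n{bad}")

    present_diag = set(raw.loc[diag, "origin"])
    missing_diag = sorted(set(raw["origin"]) - present_diag)
    if missing_diag:
        extra = pd.DataFrame(
            {"origin": missing_diag, "destination": missing_diag, "km": 0.0}
        )
        raw = pd.concat([raw, extra], ignore_index=True)
    return DistanceMatrix(raw, n_synthesized_diagonal=len(missing_diag))


class RegionMap:
    """Municipality -> (state, health region) lookup.

    Health regions are local networks of facilities spanning several
    municipalities; each region nests inside exactly one state, and each
    municipality belongs to exactly one region.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame[["muni", "state", "region"]].astype(str).reset_index(drop=True)
        dup = frame["muni"].duplicated()
        if dup.any():
            raise ValueError(
                f"municipalities mapped more than once: {sorted(frame.loc[dup, 'muni'])}"
            )
        span = frame.groupby("region")["state"].nunique()
        bad_regions = span[span > 1].index.tolist()
        if bad_regions:
            raise ValueError(f"health regions spanning multiple states: {bad_regions}")
        self._frame = frame
        self._state = frame.set_index("muni")["state"]
        self._region = frame.set_index("muni")["region"]

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def state_of(self, muni: str) -> str:
        return str(self._state.at[muni])

    def region_of(self, muni: str) -> str:
        return str(self._region.at[muni])

    def munis(self) -> list[str]:
        return self._frame["muni"].tolist()

    def write(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)


def read_region_map(path: str | Path) -> RegionMap:
    raw = pd.read_csv(path, dtype=str)
    needed = {"muni", "state", "region"}
    if not needed.issubset(raw.columns):
        raise SchemaError(
            f"region file {path} needs columns {sorted(needed)}; found {list(raw.columns)}"
        )
    return RegionMap(raw)


def read_census(path: str | Path) -> pd.DataFrame:
    """Read municipal socioeconomic covariates.

    One row per municipality (duplicates fatal); indicator columns are
    numeric with blanks kept as missing, and rows with a missing indicator
    are retained — covariates are dropped pairwise per regression, never
    globally.
    """
    raw = pd.read_csv(path, dtype={"muni": str})
    if "muni" not in raw.columns:
        raise SchemaError(f"census file {path} needs a 'muni' column")
    dup = raw["muni"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate census municipalities: {sorted(raw.loc[dup, 'muni'])}"
        )
    for col in raw.columns:
        if col != "muni":
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return raw.reset_index(drop=True)


def attach_distance(births: pd.DataFrame, dmat: DistanceMatrix) -> tuple[pd.DataFrame, int]:
    """Annotate a birth registry with traveled kilometres.

    Adds ``traveled`` (residence != birthplace, string inequality) and
    ``distance_km`` (0 for non-travelers; NaN for traveler pairs absent from
    the matrix). Returns the annotated frame and the count of unresolved
    traveler pairs.
    """
    out = births.copy()
    out["traveled"] = (out["residence_muni"] != out["birth_muni"]).astype(bool)
    merged = out.merge(
        dmat.frame,
        how="left",
        left_on=["residence_muni", "birth_muni"],
        right_on=["origin", "destination"],
    ).drop(columns=["origin", "destination"])
    merged.loc[~merged["traveled"], "km"] = 0.0
    merged = merged.rename(columns={"km": "distance_km"})
    n_missing = int((merged["traveled"] & merged["distance_km"].isna()).sum())
    return merged, n_missing
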