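"""Fossil occurrence tables: reading, filtering, and replication.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns listed in :data:`CORE_COLUMNS` (one row per occurrence).  Ages are
in Ma before present; ``min_ma <= max_ma`` bracket each occurrence's
stratigraphic age uncertainty.  Columns beyond the core schema are carried
through untouched.

Two on-disk dialects are supported:

``pbdb_csv``
    Comma-separated, Paleobiology-Database-style download columns
    (``accepted_name``, ``genus``, ``family``, ``min_ma``, ``max_ma``,
    ``environment``, ``lng``, ``lat``, ``collection_no``,
    ``primary_reso``, ``flags``).

``pyrate_table``
    Tab-separated occurrence table with columns ``Species``, ``Status``
    (``extinct``/``extant``), ``min_age``, ``max_age``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

__all__ = [
    "CORE_COLUMNS",
    "AgeReplicate",
    "SubsetPartition",
    "read_occurrences",
    "write_occurrences",
    "validate_occurrences",
    "filter_occurrences",
    "mark_extant",
    "resample_ages",
    "split_subsets",
]

CORE_COLUMNS = (
    "occurrence_id",
    "species",
    "genus",
    "family",
    "min_ma",
    "max_ma",
    "environment",
    "lng",
    "lat",
    "site",
    "qualifier",
    "accepted",
    "extant",
)

_PBDB_REQUIRED = (
    "accepted_name",
    "genus",
    "family",
    "min_ma",
    "max_ma",
    "environment",
    "lng",
    "lat",
    "collection_no",
    "primary_reso",
    "flags",
)

_PYRATE_REQUIRED = ("Species", "Status", "min_age", "max_age")

#: recognized keys for :func:`filter_occurrences`
_FILTER_RULES = frozenset(
    {
        "drop_qualified",
        "accepted_only",
        "environment_in",
        "family_in",
        "lng_window",
        "co_occurrence",
        "environment_per_species",
    }
)


@dataclass(frozen=True)
class AgeReplicate:
    """One resolution of all occurrence ages within their stratigraphic bounds."""

    replicate_index: int
    ages: pd.Series  # indexed by occurrence_id

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ConfigError("replicate_index must be >= 1")


@dataclass(frozen=True)
class SubsetPartition:
    """Species-level partition of a dataset into near-equal subsets."""

    n_subsets: int
    assignment: dict = field(repr=False)  # species -> subset index (0-based)

    def species_in(self, subset: int) -> list:
        return sorted(s for s, i in self.assignment.items() if i == subset)


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().casefold()
    return s not in {"", "0", "false", "no", "n", "nan", "none"}


def _qualifier_from_reso(reso) -> str:
    s = str(reso).strip().casefold().rstrip(".")
    if s in {"aff", "cf"}:
        return s
    return "none"


def validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    """Check core-schema invariants; returns the table unchanged."""
    for col in CORE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    if df["occurrence_id"].duplicated().any():
        raise FormatError("occurrence_id values must be unique")
    if len(df):
        empty = df["species"].astype(str).str.strip() == ""
        if empty.any():
            raise FormatError(f"empty species name at row {int(np.flatnonzero(empty)[0])}")
        bad = (df["max_ma"] < df["min_ma"]) | (df["min_ma"] < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"max_ma < min_ma (or negative age) at row {row}")
    return df


def read_occurrences(path, dialect: str = "pbdb_csv") -> pd.DataFrame:
    """Read an occurrence table in one of the supported dialects."""
    if dialect == "pbdb_csv":
        raw = pd.read_csv(path)
        missing = [c for c in _PBDB_REQUIRED if c not in raw.columns]
        if missing:
            raise FormatError(f"missing required column: {missing[0]}")
        df = pd.DataFrame(
            {
                "occurrence_id": raw["occurrence_no"]
                if "occurrence_no" in raw.columns
                else np.arange(len(raw)),
                "species": raw["accepted_name"].astype(str),
                "genus": raw["genus"].astype(str),
                "family": raw["family"].astype(str),
                "min_ma": _parse_age(raw["min_ma"]),
                "max_ma": _parse_age(raw["max_ma"]),
                "environment": raw["environment"].astype(str),
                "lng": pd.to_numeric(raw["lng"]),
                "lat": pd.to_numeric(raw["lat"]),
                "site": raw["collection_no"],
                "qualifier": raw["primary_reso"].map(_qualifier_from_reso),
                "accepted": raw["flags"].map(_parse_bool),
                "extant": raw["is_extant"].map(_parse_bool)
                if "is_extant" in raw.columns
                else False,
            }
        )
        extra = [c for c in raw.columns if c not in _PBDB_REQUIRED + ("occurrence_no", "is_extant")]
        for c in extra:
            df[c] = raw[c]
    elif dialect == "pyrate_table":
        raw = pd.read_csv(path, sep="\t")
        missing = [c for c in _PYRATE_REQUIRED if c not in raw.columns]
        if missing:
            raise FormatError(f"missing required column: {missing[0]}")
        species = raw["Species"].astype(str)
        df = pd.DataFrame(
            {
                "occurrence_id": np.arange(len(raw)),
                "species": species,
                "genus": species.str.split().str[0],
                "family": raw["Family"].astype(str) if "Family" in raw.columns else "",
                "min_ma": _parse_age(raw["min_age"]),
                "max_ma": _parse_age(raw["max_age"]),
                "environment": "",
                "lng": np.nan,
                "lat": np.nan,
                "site": -1,
                "qualifier": "none",
                "accepted": True,
                "extant": raw["Status"].astype(str).str.strip().str.casefold()
                == "extant",
            }
        )
    else:
        raise ConfigError(f"unknown dialect: {dialect!r}")
    return validate_occurrences(df)


def _parse_age(col: pd.Series) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise FormatError(f"unparsable age at row {row}")
    return out.astype(float)


def write_occurrences(df: pd.DataFrame, path, dialect: str = "pbdb_csv") -> None:
    """Write an occurrence table, round-trippable by :func:`read_occurrences`."""
    validate_occurrences(df)
    if dialect == "pbdb_csv":
        out = pd.DataFrame(
            {
                "occurrence_no": df["occurrence_id"],
                "accepted_name": df["species"],
                "genus": df["genus"],
                "family": df["family"],
                "min_ma": df["min_ma"],
                "max_ma": df["max_ma"],
                "environment": df["environment"],
                "lng": df["lng"],
                "lat": df["lat"],
                "collection_no": df["site"],
                "primary_reso": df["qualifier"].where(df["qualifier"] != "none", ""),
                "flags": df["accepted"].astype(int),
                "is_extant": df["extant"].astype(int),
            }
        )
        out.to_csv(path, index=False)
    elif dialect == "pyrate_table":
        out = pd.DataFrame(
            {
                "Species": df["species"],
                "Status": np.where(df["extant"], "extant", "extinct"),
                "min_age": df["min_ma"],
                "max_age": df["max_ma"],
                "Family": df["family"],
            }
        )
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ConfigError(f"unknown dialect: {dialect!r}")


def _is_qualified(df: pd.DataFrame) -> pd.Series:
    # a " cf. "/" aff. " token inside the name also counts as qualified
    by_column = df["qualifier"].isin(["aff", "cf"])
    name = " " + df["species"].astype(str) + " "
    by_name = name.str.contains(" cf. ", regex=False) | name.str.contains(
        " aff. ", regex=False
    )
    return by_column | by_name


def filter_occurrences(df: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Apply a conjunction of filter rules, returning a new table.

    Recognized rules: ``drop_qualified`` (bool), ``accepted_only`` (bool),
    ``environment_in`` (set of labels), ``family_in`` (set), ``lng_window``
    ((lo, hi) closed interval; lo > hi wraps across the antimeridian),
    ``co_occurrence`` (reference family: keep only records at sites where
    that family also occurs), ``environment_per_species`` (bool: apply the
    environment rule at species level — keep all records of any species
    with at least one matching occurrence).
    """
    unknown = set(rules) - _FILTER_RULES
    if unknown:
        raise ConfigError(f"unknown filter rule(s): {sorted(unknown)}")
    keep = pd.Series(True, index=df.index)
    if rules.get("drop_qualified"):
        keep &= ~_is_qualified(df)
    if rules.get("accepted_only"):
        keep &= df["accepted"].astype(bool)
    if "environment_in" in rules:
        allowed = set(rules["environment_in"])
        match = df["environment"].isin(allowed)
        if rules.get("environment_per_species"):
            ok_species = set(df.loc[match, "species"])
            keep &= df["species"].isin(ok_species)
        else:
            keep &= match
    if "family_in" in rules:
        keep &= df["family"].isin(set(rules["family_in"]))
    if "lng_window" in rules:
        lo, hi = rules["lng_window"]
        lng = df["lng"]
        if lo <= hi:
            keep &= (lng >= lo) & (lng <= hi)
        else:  # wraparound window
            keep &= (lng >= lo) | (lng <= hi)
    if "co_occurrence" in rules:
        ref = rules["co_occurrence"]
        ref_sites = set(df.loc[df["family"] == ref, "site"])
        keep &= df["site"].isin(ref_sites)
    return df.loc[keep].copy()


def mark_extant(df: pd.DataFrame, extant_names) -> pd.DataFrame:
    """Set the extant flag exactly for species in ``extant_names``.

    Matching is exact on normalized (whitespace-collapsed, case-folded)
    binomials.  Returns a new table.
    """
    normalized = {_normalize_name(n) for n in extant_names}
    out = df.copy()
    out["extant"] = out["species"].map(_normalize_name).isin(normalized)
    return out


def resample_ages(df: pd.DataFrame, n_replicates: int, seed: int) -> list:
    """Draw ``n_replicates`` age replicates, each age uniform in [min_ma, max_ma]."""
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    lo = df["min_ma"].to_numpy(float)
    hi = df["max_ma"].to_numpy(float)
    out = []
    for r in range(1, n_replicates + 1):
        u = rng.random(len(df))
        ages = lo + u * (hi - lo)
        out.append(
            AgeReplicate(r, pd.Series(ages, index=df["occurrence_id"].to_numpy(), name="age"))
        )
    return out


def split_subsets(df: pd.DataFrame, n_subsets: int, seed: int) -> SubsetPartition:
    """Randomly assign species to ``n_subsets`` groups of near-equal size.

    All occurrences of a species share a subset; subset species counts
    differ by at most one (remainder species go one-per-subset to
    randomly chosen subsets).
    """
    species = sorted(df["species"].astype(str).unique())
    if n_subsets < 1 or n_subsets > len(species):
        raise ConfigError(
            f"n_subsets must be in [1, {len(species)}], got {n_subsets}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(species))
    base, rem = divmod(len(species), n_subsets)
    sizes = np.full(n_subsets, base, dtype=int)
    if rem:
        sizes[rng.choice(n_subsets, size=rem, replace=False)] += 1
    assignment = {}
    pos = 0
    for subset, size in enumerate(sizes):
        for k in order[pos : pos + size]:
            assignment[species[k]] = subset
        pos += size
    return SubsetPartition(n_subsets=n_subsets, assignment=assignment)
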