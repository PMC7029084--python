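"""Reading, validation and preprocessing of species × trait tables.

A trait table holds one row per species with a taxonomic group label, adult
body mass (grams) and a set of life-history trait columns, each with a
declared unit.  All downstream statistics work on log10-transformed values,
so zeros and negative cells are treated as missing (with a warning) rather
than as errors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column names inside a TraitTable frame
SPECIES = "species"
GROUP = "group"
BODY_MASS = "body_mass"

_WS = re.compile(r"\s+")


class InsufficientSample(ValueError):
    """Raised when too few complete records exist for a statistic."""


def normalize_species(name: str) -> str:
    """Trim and collapse internal whitespace runs; no synonym resolution."""
    return _WS.sub(" ", str(name).strip())


@dataclass(frozen=True)
class GroupSpec:
    """An analysis group pooling one or more taxonomic labels."""

    name: str
    member_groups: frozenset[str]

    def __post_init__(self):
        if not self.member_groups:
            raise ValueError(f"GroupSpec {self.name!r}: member_groups is empty")

    @classmethod
    def of(cls, name: str, *members: str) -> "GroupSpec":
        return cls(name, frozenset(members) if members else frozenset({name}))


@dataclass
class TraitTable:
    """Species × trait observations with group labels and units.

    ``df`` is indexed 0..n-1 and has columns ``species``, ``group``,
    ``body_mass`` plus one column per trait; missing values are NaN.
    ``units`` maps every trait column (and body mass) to a unit string.
    """

    df: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        dup = self.df[SPECIES][self.df[SPECIES].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate species name: {dup.iloc[0]!r}")
        for col in self.trait_names + [BODY_MASS]:
            self.units.setdefault(col, "unknown")
            vals = self.df[col].to_numpy(dtype=float)
            bad = np.isfinite(vals) & (vals <= 0)
            if bad.any():
                raise ValueError(
                    f"non-positive values remain in column {col!r}; "
                    "clean them through read_trait_table first"
                )

    @property
    def species(self) -> list[str]:
        return list(self.df[SPECIES])

    @property
    def trait_names(self) -> list[str]:
        reserved = {SPECIES, GROUP, BODY_MASS}
        return [c for c in self.df.columns if c not in reserved]

    def __len__(self) -> int:
        return len(self.df)

    def trait_values(self, trait: str) -> np.ndarray:
        return self.df[trait].to_numpy(dtype=float)


def _coerce_positive(series: pd.Series, col: str) -> pd.Series:
    """Parse to float; non-numeric or non-positive entries become NaN."""
    out = pd.to_numeric(series, errors="coerce")
    bad_numeric = series.notna() & (series.astype(str).str.strip() != "") & out.isna()
    nonpos = out.notna() & (out <= 0)
    if bad_numeric.any():
        log.warning("column %r: %d non-numeric cell(s) set to missing", col,
                    int(bad_numeric.sum()))
    if nonpos.any():
        log.warning("column %r: %d non-positive cell(s) set to missing "
                    "(log10 undefined)", col, int(nonpos.sum()))
    return out.mask(nonpos)


def read_trait_table(
    path,
    schema: dict,
    sep: str | None = None,
) -> TraitTable:
    """Read a delimited text file into a :class:`TraitTable`.

    ``schema`` maps canonical names to file columns::

        {"species": "Species", "group": "Order", "body_mass": "BM_g",
         "traits": {"clutch_size": "CS", ...},
         "units": {"body_mass": "g", "clutch_size": "count", ...}}

    ``group`` is optional (defaults to a single group "all"). Row count is
    preserved; dirty cells become missing values, never dropped rows.
    """
    if "species" not in schema:
        raise ValueError("schema must name a species column")
    traits: dict[str, str] = dict(schema.get("traits", {}))
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True,
                      na_values=["NA", ""])
    if schema["species"] not in raw.columns:
        raise ValueError(f"species column {schema['species']!r} not in file")
    out = pd.DataFrame()
    out[SPECIES] = raw[schema["species"]].map(normalize_species)
    if "group" in schema and schema["group"] in raw.columns:
        out[GROUP] = raw[schema["group"]].fillna("unknown").map(str.strip)
    else:
        out[GROUP] = "all"
    if "body_mass" in schema and schema["body_mass"] in raw.columns:
        out[BODY_MASS] = _coerce_positive(raw[schema["body_mass"]], BODY_MASS)
    else:
        out[BODY_MASS] = np.nan
    for name, col in traits.items():
        if col not in raw.columns:
            raise ValueError(f"trait column {col!r} (for {name!r}) not in file")
        out[name] = _coerce_positive(raw[col], name)
    units = dict(schema.get("units", {}))
    return TraitTable(out, units)


def write_trait_table(table: TraitTable, path, sep: str = ",") -> None:
    """Write a table back to delimited text (missing values as empty cells)."""
    table.df.to_csv(path, sep=sep, index=False, na_rep="")


def harmonize_min_max(
    table: TraitTable, pairs: list[tuple[str, str, str]]
) -> TraitTable:
    """Collapse (min, max) trait column pairs into their arithmetic mean.

    Where only one side is present the single value is used; where both are
    missing the result is missing.  A reversed pair (min > max) is averaged
    anyway, with a warning.  Idempotent: applying the same pairs to a table
    where only the out-columns remain is a no-op.
    """
    df = table.df.copy()
    units = dict(table.units)
    for lo, hi, out in pairs:
        if lo not in df.columns or hi not in df.columns:
            if out in df.columns:  # already harmonized
                continue
            raise ValueError(f"min/max pair ({lo!r}, {hi!r}) not in table")
        a = df[lo].to_numpy(dtype=float)
        b = df[hi].to_numpy(dtype=float)
        rev = np.isfinite(a) & np.isfinite(b) & (a > b)
        if rev.any():
            log.warning("pair (%s, %s): %d row(s) with min > max; "
                        "mean taken anyway", lo, hi, int(rev.sum()))
        both = np.column_stack([a, b])
        any_present = np.isfinite(both).any(axis=1)
        merged = np.full(len(df), np.nan)
        if any_present.any():
            merged[any_present] = np.nanmean(both[any_present], axis=1)
        df[out] = merged
        units[out] = units.get(out) or units.get(lo, "unknown")
        df = df.drop(columns=[c for c in (lo, hi) if c != out])
        units.pop(lo, None)
        units.pop(hi, None)
    return TraitTable(df, units)


def subset_group(table: TraitTable, spec: GroupSpec) -> TraitTable:
    """Rows whose group label belongs to ``spec.member_groups``."""
    mask = table.df[GROUP].isin(spec.member_groups)
    sub = table.df[mask].reset_index(drop=True)
    if len(sub) == 0:
        log.warning("group %r: empty subset", spec.name)
    return TraitTable(sub, dict(table.units))


def paired_log10(
    table: TraitTable, trait: str, min_n: int = 3
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """log10(body mass), log10(trait) for species with both recorded.

    Returns ``(x, y, species)`` in table row order. Raises
    :class:`InsufficientSample` below ``min_n`` complete pairs, because the
    downstream regressions must refuse such samples.
    """
    if trait not in table.trait_names:
        raise KeyError(f"trait {trait!r} not in table")
    m = table.df[BODY_MASS].to_numpy(dtype=float)
    t = table.df[trait].to_numpy(dtype=float)
    ok = np.isfinite(m) & np.isfinite(t)
    if ok.sum() < min_n:
        raise InsufficientSample(
            f"trait {trait!r}: only {int(ok.sum())} complete (mass, trait) "
            f"pairs, need {min_n}"
        )
    sp = [s for s, k in zip(table.species, ok) if k]
    return np.log10(m[ok]), np.log10(t[ok]), sp
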