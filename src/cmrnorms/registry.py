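"""The packaged normative-table store and the measurement classification API.

Tables live as CSV files with JSON sidecars under ``cmrnorms/data/tables``.
Four kinds exist:

``ranges``
    Rows of (parameter, stratum, n, mean, SD, lower, upper) — either
    single-study mean ± 2 SD rows or pooled multi-study rows.
``lms``
    Pediatric LMS grids (covariate, L, M, S), optionally with the printed
    centile columns kept for verification.
``regression``
    Predicted-value regressions on BSA with an SD of residuals.
``centile_table``
    Printed centile-by-height/BSA lookup tables.

:meth:`Registry.select_reference` routes a measurement record to the most
specific applicable entry (sex+age+ethnicity beats sex+age beats sex beats
unstratified); :meth:`Registry.classify` turns that into a status, z-score
and centile.  Ties between equally specific entries raise a configuration
error naming both entries rather than guessing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cmrnorms.growth import CentileTable, LMSModel, RegressionZModel, centile_band
from scipy import stats as _stats

__all__ = [
    "ParameterDef", "Stratum", "StudySummary", "ReferenceRange",
    "MeasurementRecord", "ClassificationResult", "Registry",
    "RegistryError", "AmbiguousReferenceError", "load_default_registry",
    "eligibility_filter",
]

SEXES = ("male", "female", "all")
ETHNICITIES = ("all", "black", "caucasian", "chinese", "latin_american",
               "south_asian", "other")
INDEXINGS = ("absolute", "per_bsa", "per_height")
CONVENTIONS = ("papillary_in_mass", "papillary_in_volume", "not_applicable")


class RegistryError(KeyError):
    """Unknown parameter or malformed table store."""


class AmbiguousReferenceError(RuntimeError):
    """Two equally specific table entries match the same record."""


@dataclass(frozen=True)
class ParameterDef:
    id: str
    name: str
    units: str
    indexing: str = "absolute"
    convention: str = "not_applicable"
    plane: str = ""

    def __post_init__(self) -> None:
        if not self.id or not self.units:
            raise ValueError("parameter id and units must be non-empty")
        if self.indexing not in INDEXINGS:
            raise ValueError(f"unknown indexing {self.indexing!r}")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass(frozen=True)
class Stratum:
    """Population slice a table row applies to.

    Age bands follow the printed closed headers ("20-29") but are
    implemented half-open [age_lo, age_hi) so adjacent bands tile the
    axis without gaps; an empty bound is unbounded.
    """

    sex: str = "all"
    age_lo: float = float("-inf")
    age_hi: float = float("inf")
    ethnicity: str = "all"
    field_strength: str | None = None
    technique: str | None = None
    group: str | None = None
    population: str = "general"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.age_lo > self.age_hi:
            raise ValueError("age_lo must be <= age_hi")

    def matches(self, record: "MeasurementRecord") -> bool:
        if self.population != "general" and record.population != self.population:
            return False
        if self.group is not None and record.group is not None \
                and record.group != self.group:
            return False
        if self.sex != "all" and record.sex not in (self.sex, None):
            return False
        if self.sex != "all" and record.sex is None:
            return False
        if record.age is not None:
            if not (self.age_lo <= record.age < self.age_hi
                    or (record.age == self.age_hi == float("inf"))):
                return False
        elif self.age_lo != float("-inf") or self.age_hi != float("inf"):
            return False
        if self.ethnicity != "all" and record.ethnicity != self.ethnicity:
            return False
        if self.field_strength is not None and record.field_strength != self.field_strength:
            return False
        if self.technique is not None and record.technique != self.technique:
            return False
        return True

    @property
    def specificity(self) -> tuple[int, ...]:
        """Lexicographic specificity: population > ethnicity > age > sex > tags."""
        return (int(self.population != "general"),
                int(self.ethnicity != "all"),
                int(self.age_lo != float("-inf") or self.age_hi != float("inf")),
                int(self.sex != "all"),
                int(self.group is not None),
                int(self.field_strength is not None) + int(self.technique is not None))


@dataclass(frozen=True)
class StudySummary:
    """One study's aggregate (n, mean, SD) for a parameter within a stratum."""

    study_id: str
    parameter_id: str
    n: int
    mean: float
    sd: float
    stratum: Stratum = field(default_factory=Stratum)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ReferenceRange:
    """A lower/upper reference limit pair with its provenance method."""

    lower: float
    upper: float
    mean: float
    sd: float | None
    n_total: int
    method: str
    precision: int = 0
    distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower limit must be <= upper limit")

    def contains(self, value: float) -> bool:
        """Limits are inclusive: a value on a printed limit is normal."""
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class MeasurementRecord:
    """A single patient measurement with the covariates tables condition on."""

    parameter_id: str
    value: float
    sex: str | None = None
    age: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    bsa: float | None = None
    ethnicity: str | None = None
    field_strength: str | None = None
    technique: str | None = None
    population: str = "general"
    group: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("measurement value must be finite")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be >= 0")

    def bsa_value(self, formula: str = "dubois") -> float | None:
        """BSA as supplied, else derived from height and weight."""
        if self.bsa is not None:
            return self.bsa
        if self.height_cm is not None and self.weight_kg is not None:
            from cmrnorms.formulas import bsa
            return bsa(self.height_cm, self.weight_kg, formula)
        return None


@dataclass(frozen=True)
class ClassificationResult:
    status: str                      # below_range | within_range | above_range | no_reference
    z: float | None = None
    centile: float | None = None
    range_used: object | None = None
    provenance: str = ""
    detail: str = ""


# --------------------------------------------------------------------------
# table-store entries


@dataclass(frozen=True)
class RangeEntry:
    table_id: str
    parameter_id: str
    stratum: Stratum
    range: ReferenceRange

    @property
    def provenance(self) -> str:
        return f"{self.table_id}:{self.parameter_id}/{self.stratum.sex}" + (
            f"/{self.stratum.group}" if self.stratum.group else "")


def eligibility_filter(study: StudySummary, per_sex: bool = False,
                       min_n: int = 40) -> tuple[bool, str]:
    """Study-inclusion rule: at least 40 subjects (per sex when stratified).

    Returns (accepted, reason).
    """
    label = "per-sex stratum" if per_sex else "study"
    if study.n >= min_n:
        return True, f"{label} n={study.n} >= {min_n}"
    return False, (f"rejected: {label} n={study.n} < minimum sample size "
                   f"{min_n} required for parametric reference ranges")


class Registry:
    """In-memory table store with routing and classification."""

    def __init__(self) -> None:
        self.parameters: dict[str, ParameterDef] = {}
        self.ranges: list[RangeEntry] = []
        self.lms_models: list[LMSModel] = []
        self.regressions: list[RegressionZModel] = []
        self.centile_tables: list[CentileTable] = []
        self.table_meta: dict[str, dict] = {}
        # printed cells kept for verification: (table_id, sex, cov, centile, value)
        self.printed_lms_cells: list[tuple[str, str, float, float, int]] = []

    # -------------------------------------------------------------- loading

    def load_dir(self, directory: Path | str) -> "Registry":
        directory = Path(directory)
        for sidecar in sorted(directory.glob("*.json")):
            meta = json.loads(sidecar.read_text())
            table_id = meta.get("table_id", sidecar.stem)
            csv_path = sidecar.with_suffix(".csv")
            if not csv_path.exists():
                raise RegistryError(f"table {table_id} has no CSV next to {sidecar}")
            self.table_meta[table_id] = meta
            kind = meta.get("kind")
            df = pd.read_csv(csv_path)
            if kind == "parameter_defs":
                self._load_parameters(df)
            elif kind == "ranges":
                self._load_ranges(table_id, df)
            elif kind == "lms":
                self._load_lms(table_id, meta, df)
            elif kind == "regression":
                self._load_regression(table_id, df)
            elif kind == "centile_table":
                self._load_centiles(table_id, meta, df)
            else:
                raise RegistryError(f"table {table_id} has unknown kind {kind!r}")
        return self

    def _load_parameters(self, df: pd.DataFrame) -> None:
        for row in df.itertuples(index=False):
            p = ParameterDef(id=row.id, name=row.name, units=row.units,
                             indexing=row.indexing, convention=row.convention,
                             plane="" if pd.isna(row.plane) else row.plane)
            if p.id in self.parameters:
                raise RegistryError(f"duplicate parameter id {p.id!r}")
            self.parameters[p.id] = p

    @staticmethod
    def _opt(v) -> str | None:
        return None if (v is None or (isinstance(v, float) and math.isnan(v))
                        or v == "") else str(v)

    def _load_ranges(self, table_id: str, df: pd.DataFrame) -> None:
        population = self.table_meta.get(table_id, {}).get("population", "general")
        if "athlete" in population:
            population = "athlete"
        else:
            population = "general"
        for row in df.itertuples(index=False):
            stratum = Stratum(
                sex=row.sex,
                age_lo=float(row.age_lo) if not pd.isna(row.age_lo) and row.age_lo != "" else float("-inf"),
                age_hi=float(row.age_hi) if not pd.isna(row.age_hi) and row.age_hi != "" else float("inf"),
                ethnicity=self._opt(row.ethnicity) or "all",
                field_strength=self._opt(row.field_strength),
                technique=self._opt(row.technique),
                group=self._opt(row.group),
                population=population,
            )
            sd = None if pd.isna(row.sd) or row.sd == "" else float(row.sd)
            rng = ReferenceRange(lower=float(row.lower), upper=float(row.upper),
                                 mean=float(row.mean), sd=sd,
                                 n_total=int(row.n), method=row.method,
                                 precision=int(row.precision),
                                 distribution=row.distribution)
            self.ranges.append(RangeEntry(table_id, row.parameter_id, stratum, rng))

    def _load_lms(self, table_id: str, meta: dict, df: pd.DataFrame) -> None:
        discordant = set(meta.get("centiles_discordant", []))
        group_cols = ["sex"] + (["site"] if "site" in df.columns else [])
        for keys, sub in df.groupby(group_cols, sort=False):
            keys = (keys,) if not isinstance(keys, tuple) else keys
            sex = keys[group_cols.index("sex")]
            site = keys[group_cols.index("site")] if "site" in group_cols else ""
            sub = sub.sort_values("covariate_value")
            grid = sub[["covariate_value", "L", "M", "S"]].to_numpy(float)
            pid = meta["parameter_id"] + (f":{site}" if site else "")
            self.lms_models.append(LMSModel(
                parameter_id=pid, covariate=meta["covariate"], sex=sex,
                grid=grid, citation=table_id, units=meta.get("units", "")))
            cent_cols = [c for c in sub.columns if c.startswith("c") and c[1:].isdigit()]
            if cent_cols and sex not in discordant:
                for _, r in sub.iterrows():
                    for c in cent_cols:
                        self.printed_lms_cells.append(
                            (table_id, sex, float(r["covariate_value"]),
                             float(c[1:]), int(r[c])))

    def _load_regression(self, table_id: str, df: pd.DataFrame) -> None:
        for row in df.itertuples(index=False):
            sd = None if pd.isna(row.sd_residuals) or row.sd_residuals == "" \
                else float(row.sd_residuals)
            self.regressions.append(RegressionZModel(
                parameter_id=row.parameter_id, intercept=float(row.intercept),
                slope=float(row.slope), transform=row.transform,
                sd_residuals=sd, site=row.site, citation=table_id,
                units=row.units))

    def _load_centiles(self, table_id: str, meta: dict, df: pd.DataFrame) -> None:
        cent_cols = [c for c in df.columns if c.startswith("c") and c[1:].isdigit()]
        for (pid, sex), sub in df.groupby(["parameter_id", "sex"], sort=False):
            sub = sub.sort_values("covariate_value")
            rows = sub[["covariate_value"] + cent_cols].to_numpy(float)
            self.centile_tables.append(CentileTable(
                parameter_id=pid, covariate=meta["covariate"], sex=sex,
                centiles=tuple(float(c[1:]) for c in cent_cols), rows=rows,
                citation=table_id, units=meta.get("units", "")))

    # -------------------------------------------------------------- routing

    def _record_covariate(self, record: MeasurementRecord, covariate: str) -> float | None:
        if covariate == "age_years":
            return record.age
        if covariate == "height_cm":
            return record.height_cm
        if covariate == "bsa_m2":
            return record.bsa_value()
        return None

    def select_reference(self, record: MeasurementRecord, *,
                         table: str | None = None):
        """Most specific applicable table entry for a record.

        Precedence across kinds: distributional growth models (LMS) beat
        regression z-models beat printed centile tables beat plain ranges
        — a model that yields a continuous z/centile is preferred over a
        band.  Within ranges, the most specific stratum wins
        (sex+age+ethnicity > sex+age > sex > all); equal specificity is a
        configuration error.  ``table`` forces a named table.
        """
        if record.parameter_id not in self.parameters:
            raise RegistryError(f"unknown parameter id {record.parameter_id!r}")

        def tbl_ok(tid: str) -> bool:
            return table is None or tid == table

        lms_hits = []
        for m in self.lms_models:
            pid, _, site = m.parameter_id.partition(":")
            if pid != record.parameter_id or not tbl_ok(m.citation):
                continue
            if site and record.site != site:
                continue
            if m.sex not in ("all", record.sex):
                continue
            cov = self._record_covariate(record, m.covariate)
            if cov is not None and m.covariate_range[0] <= cov <= m.covariate_range[1]:
                lms_hits.append(m)
        if len(lms_hits) > 1:
            names = ", ".join(f"{m.citation}:{m.parameter_id}/{m.sex}" for m in lms_hits)
            raise AmbiguousReferenceError(
                f"multiple LMS models match {record.parameter_id}: {names}; "
                "specify the site")
        if lms_hits:
            return lms_hits[0]
        reg_hits = [m for m in self.regressions
                    if m.parameter_id == record.parameter_id and tbl_ok(m.citation)
                    and m.sd_residuals is not None
                    and (record.site is None or m.site == record.site)
                    and record.bsa_value() is not None]
        if len(reg_hits) > 1:
            names = ", ".join(f"{m.citation}:{m.site}" for m in reg_hits)
            raise AmbiguousReferenceError(
                f"multiple regression models match {record.parameter_id}: {names}; "
                "specify the site")
        if reg_hits:
            return reg_hits[0]
        for t in self.centile_tables:
            if t.parameter_id != record.parameter_id or not tbl_ok(t.citation):
                continue
            if t.sex not in ("all", record.sex):
                continue
            cov = self._record_covariate(record, t.covariate)
            if cov is not None and t.covariate_range[0] <= cov <= t.covariate_range[1]:
                return t

        candidates = [e for e in self.ranges
                      if e.parameter_id == record.parameter_id
                      and tbl_ok(e.table_id) and e.stratum.matches(record)]
        if not candidates:
            return None
        best = max(c.stratum.specificity for c in candidates)
        top = [c for c in candidates if c.stratum.specificity == best]
        if len(top) > 1:
            names = ", ".join(t.provenance for t in top)
            raise AmbiguousReferenceError(
                f"equally specific references for {record.parameter_id}: {names}; "
                "disambiguate via the technique/group fields or force a table")
        return top[0]

    # ---------------------------------------------------------- classification

    def classify(self, record: MeasurementRecord, *,
                 table: str | None = None) -> ClassificationResult:
        """Classify a measurement against the most specific reference.

        Returns ``no_reference`` (not an exception) when nothing matches.
        Range limits are inclusive; for distributional models the status is
        judged at z = ±2, the convention the printed tables equate with
        their reference limits.
        """
        try:
            ref = self.select_reference(record, table=table)
        except AmbiguousReferenceError:
            raise
        if ref is None:
            return ClassificationResult(status="no_reference",
                                        detail="no applicable table entry")

        if isinstance(ref, RangeEntry):
            rng = ref.range
            if rng.distribution != "normal" or rng.sd in (None, 0):
                z = None
            else:
                z = (record.value - rng.mean) / rng.sd
            if rng.contains(record.value):
                status = "within_range"
            elif record.value < rng.lower:
                status = "below_range"
            else:
                status = "above_range"
            return ClassificationResult(status=status, z=z, range_used=rng,
                                        provenance=ref.provenance)

        if isinstance(ref, LMSModel):
            cov = self._record_covariate(record, ref.covariate)
            z = ref.z(record.value, cov)
            centile = ref.centile_of(record.value, cov)
            status = ("below_range" if z < -2.0 else
                      "above_range" if z > 2.0 else "within_range")
            return ClassificationResult(status=status, z=z, centile=centile,
                                        range_used=ref,
                                        provenance=f"{ref.citation}:{ref.sex}")

        if isinstance(ref, RegressionZModel):
            from cmrnorms.growth import regression_z
            z, predicted = regression_z(record.value, record.bsa_value(), ref)
            status = ("below_range" if z < -2.0 else
                      "above_range" if z > 2.0 else "within_range")
            return ClassificationResult(
                status=status, z=z, range_used=ref,
                provenance=f"{ref.citation}:{ref.site}",
                detail=f"predicted={predicted:.2f} {ref.units}")

        if isinstance(ref, CentileTable):
            cov = self._record_covariate(record, ref.covariate)
            band, approx = centile_band(ref, cov, record.value)
            status = ("below_range" if band.startswith("<") else
                      "above_range" if band.startswith(">") else "within_range")
            return ClassificationResult(status=status, centile=approx,
                                        range_used=ref,
                                        provenance=f"{ref.citation}:{ref.sex}",
                                        detail=f"band {band}")

        raise TypeError(f"unexpected reference type {type(ref)!r}")


def load_default_registry(extra_dir: Path | str | None = None) -> Registry:
    """Registry loaded from the packaged tables, plus an optional user directory."""
    reg = Registry()
    with resources.as_file(resources.files("cmrnorms") / "data" / "tables") as p:
        reg.load_dir(p)
    if extra_dir is not None:
        reg.load_dir(extra_dir)
    return reg
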