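"""Data model and CSV I/O for case-series and reference-population tables.

A *case series* is the tabulation of disease cases over the levels of several
categorical determinants (age group, gender, education, comorbidities).  A
*population reference* maps each determinant level to its proportion in the
general population.  Together they are the inputs of the Bayes posterior-risk
computation in :mod:`bayesrisk.bayes_risk`.

Conventions
-----------
* Proportions are stored internally as fractions in ``[0, 1]``; percentages
  exist only at the I/O and rendering boundaries.
* Level labels are Unicode-NFC normalized on read, so en-dash range labels
  such as ``"60–69 years"`` match exactly regardless of how the CSV was
  produced.
* A factor is *exhaustive* when its levels are mutually exclusive and cover
  every case (its counts must sum to the number of cases).  Comorbidities are
  non-exhaustive: a patient may carry several, or none.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import FormatError, ValidationError

__all__ = [
    "LevelSummary",
    "FactorSummary",
    "CaseSeries",
    "PopulationReference",
    "read_case_table",
    "write_case_table",
    "read_population_reference",
    "load_hail_cases",
    "load_hail_clinical",
    "load_hail_population",
    "load_hail_published_posteriors",
]

_CASE_COLUMNS = ("factor", "level", "count", "exhaustive")
_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s.strip())


@dataclass(frozen=True)
class LevelSummary:
    """One determinant level among the cases.

    ``case_proportion`` is the fraction of cases exhibiting the level,
    i.e. the conditional probability P(RF | disease).
    """

    factor_name: str
    level_label: str
    case_count: int
    case_proportion: float

    def __post_init__(self) -> None:
        if self.case_count < 0:
            raise ValidationError(
                f"negative count {self.case_count} for level {self.level_label!r}"
            )
        if not 0.0 <= self.case_proportion <= 1.0:
            raise ValidationError(
                f"case proportion {self.case_proportion} outside [0, 1] "
                f"for level {self.level_label!r}"
            )


@dataclass(frozen=True)
class FactorSummary:
    """A categorical determinant: its levels and whether they are exhaustive."""

    name: str
    exhaustive: bool
    levels: tuple[LevelSummary, ...]


@dataclass(frozen=True)
class CaseSeries:
    """Counts of disease cases per level of each categorical determinant."""

    disease_label: str
    n_cases: int
    n_screened: int
    factors: tuple[FactorSummary, ...]

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValidationError("n_cases must be positive")
        if self.n_screened < self.n_cases:
            raise ValidationError(
                f"n_screened ({self.n_screened}) smaller than n_cases ({self.n_cases})"
            )
        seen: set[tuple[str, str]] = set()
        for factor in self.factors:
            for lev in factor.levels:
                key = (factor.name, lev.level_label)
                if key in seen:
                    raise ValidationError(f"duplicate level {key!r}")
                seen.add(key)
            if factor.exhaustive:
                total = sum(lev.case_count for lev in factor.levels)
                if total != self.n_cases:
                    raise ValidationError(
                        f"exhaustive factor {factor.name!r} counts sum to {total}, "
                        f"expected n_cases={self.n_cases}"
                    )

    def factor(self, name: str) -> FactorSummary:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def iter_levels(self) -> Iterator[LevelSummary]:
        for f in self.factors:
            yield from f.levels


@dataclass(frozen=True)
class PopulationReference:
    """Proportion of the general population in each determinant level.

    Houses the marginal P(RF) of the Bayes computation.  Levels of one
    exhaustive factor need *not* sum to 1: a reference table restricted to
    adults covers only part of the full population pyramid.
    """

    entries: Mapping[str, float]
    source_note: str = ""

    def __post_init__(self) -> None:
        for level, p in self.entries.items():
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"population proportion {p} for level {level!r} outside (0, 1]"
                )

    def proportion(self, level_label: str) -> float:
        label = _nfc(level_label)
        try:
            return self.entries[label]
        except KeyError:
            raise ValidationError(
                f"no population proportion for level {label!r}"
            ) from None

    def __contains__(self, level_label: str) -> bool:
        return _nfc(level_label) in self.entries


def _build_case_series(
    rows: Iterable[tuple[str, str, int, bool]],
    *,
    n_cases: int | None,
    n_screened: int | None,
    disease_label: str,
) -> CaseSeries:
    order: list[str] = []
    grouped: dict[str, list[tuple[str, int]]] = {}
    exhaustive: dict[str, bool] = {}
    for factor, level, count, exh in rows:
        if factor not in grouped:
            grouped[factor] = []
            exhaustive[factor] = exh
            order.append(factor)
        elif exhaustive[factor] != exh:
            raise ValidationError(
                f"inconsistent exhaustive flag within factor {factor!r}"
            )
        grouped[factor].append((level, count))

    if n_cases is None:
        sums = {
            name: sum(c for _, c in grouped[name])
            for name in order
            if exhaustive[name]
        }
        if not sums:
            raise ValidationError(
                "n_cases cannot be inferred: no exhaustive factor present"
            )
        if len(set(sums.values())) > 1:
            raise ValidationError(
                f"exhaustive factors disagree on the number of cases: {sums}"
            )
        n_cases = next(iter(sums.values()))

    factors = tuple(
        FactorSummary(
            name=name,
            exhaustive=exhaustive[name],
            levels=tuple(
                LevelSummary(name, level, count, count / n_cases)
                for level, count in grouped[name]
            ),
        )
        for name in order
    )
    return CaseSeries(
        disease_label=disease_label,
        n_cases=n_cases,
        n_screened=n_screened if n_screened is not None else n_cases,
        factors=factors,
    )


def read_case_table(
    path: str | Path,
    *,
    n_cases: int | None = None,
    n_screened: int | None = None,
    disease_label: str = "disease",
) -> CaseSeries:
    """Read a case-series CSV (columns ``factor,level,count,exhaustive``).

    When ``n_cases`` is omitted it is inferred from the exhaustive factors,
    which must all sum to the same total.  ``n_screened`` defaults to
    ``n_cases`` (a pure case series with no screening denominator).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        fields = [_nfc(c).lower() for c in reader.fieldnames]
        missing = [c for c in _CASE_COLUMNS if c not in fields]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        rows: list[tuple[str, str, int, bool]] = []
        for lineno, raw in enumerate(reader, start=2):
            rec = {_nfc(k).lower(): (v or "") for k, v in raw.items() if k}
            try:
                count = int(rec["count"])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {rec['count']!r}"
                ) from None
            if count < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {count}")
            flag = rec["exhaustive"].strip().lower()
            if flag in _TRUE:
                exh = True
            elif flag in _FALSE:
                exh = False
            else:
                raise FormatError(
                    f"{path}:{lineno}: exhaustive flag {rec['exhaustive']!r} "
                    "is not a boolean"
                )
            rows.append((_nfc(rec["factor"]), _nfc(rec["level"]), count, exh))
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return _build_case_series(
        rows, n_cases=n_cases, n_screened=n_screened, disease_label=disease_label
    )


def write_case_table(series: CaseSeries, path: str | Path) -> None:
    """Write a :class:`CaseSeries` back to the canonical CSV layout."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CASE_COLUMNS)
        for factor in series.factors:
            for lev in factor.levels:
                writer.writerow(
                    [factor.name, lev.level_label, lev.case_count,
                     "true" if factor.exhaustive else "false"]
                )


def _read_level_value_csv(
    path: str | Path, value_column: str, *, default_units: str
) -> dict[str, float]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        fields = [_nfc(c).lower() for c in reader.fieldnames]
        for col in ("level", value_column):
            if col not in fields:
                raise FormatError(f"{path}: missing column {col!r}")
        out: dict[str, float] = {}
        for lineno, raw in enumerate(reader, start=2):
            rec = {_nfc(k).lower(): (v or "") for k, v in raw.items() if k}
            units = rec.get("units", "").strip().lower() or default_units
            text = rec[value_column].strip()
            if text.endswith("%"):
                units = "percent"
                text = text[:-1]
            try:
                value = float(text)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric {value_column} {text!r}"
                ) from None
            if units == "percent":
                value /= 100.0
            elif units != "fraction":
                raise FormatError(f"{path}:{lineno}: unknown units {units!r}")
            level = _nfc(rec["level"])
            if level in out:
                raise ValidationError(f"{path}:{lineno}: duplicate level {level!r}")
            out[level] = value
    if not out:
        raise FormatError(f"{path}: no data rows")
    return out


def read_population_reference(
    path: str | Path, *, default_units: str = "percent", source_note: str = ""
) -> PopulationReference:
    """Read a reference-population CSV (columns ``level,proportion[,units]``).

    Values may be percentages or fractions; a per-row ``units`` column or a
    trailing ``%`` overrides ``default_units``.  Proportions are validated to
    lie in ``(0, 1]`` after normalization.
    """
    entries = _read_level_value_csv(path, "proportion", default_units=default_units)
    return PopulationReference(entries=entries, source_note=source_note)


# --------------------------------------------------------------------------
# Packaged study tables: the Hail-region glaucoma cross-section (200 cases
# among 9407 screened outpatients) with its published reference-population
# proportions and posterior risks.

def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_hail_cases(n_screened: int = 9407) -> CaseSeries:
    """Case counts per determinant level for the Hail glaucoma case series."""
    return read_case_table(
        _data_path("hail_cases.csv"),
        n_screened=n_screened,
        disease_label="glaucoma",
    )


def load_hail_clinical() -> CaseSeries:
    """Clinical-presentation counts (symptoms, type, duration) for the cases."""
    return read_case_table(
        _data_path("hail_clinical.csv"), n_screened=9407, disease_label="glaucoma"
    )


def load_hail_population() -> PopulationReference:
    """General-population proportions per level (UN statistics compilation)."""
    return read_population_reference(
        _data_path("hail_population.csv"), source_note="Unstats.un.org"
    )


def load_hail_published_posteriors() -> dict[str, float]:
    """Published posterior glaucoma risks per level, as fractions."""
    return _read_level_value_csv(
        _data_path("hail_published_posteriors.csv"), "posterior",
        default_units="percent",
    )
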