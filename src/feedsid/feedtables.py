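"""Data model and CSV I/O for feed-evaluation tables.

The package works with four kinds of tabular records:

* ingredient lots (proximate composition + 18-amino-acid profile, air-dry basis),
* analyzed diet assays (air-dry basis, with dry matter and TiO2 marker inclusion),
* per pig-period ileal digesta assays (dry-matter basis),
* basal endogenous ileal losses (g per kg of dry-matter intake).

A transcription of the published summary tables for a ten-lot rapeseed-cake
feeding study is bundled under :mod:`feedsid.data` and exposed through
:func:`fixtures`; it is the reference dataset used throughout the test-suite
and by the ``reproduce-paper`` pipeline command.

All CSV files are comma-separated UTF-8 with a mandatory header row; empty
cells encode missing values and are surfaced as *absent* keys, never as zero.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "PROXIMATE_COMPONENTS",
    "COMPONENTS",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "IngredientSample",
    "DietAssay",
    "DigestaObservation",
    "EndogenousLosses",
    "FixtureBundle",
    "read_table",
    "write_table",
    "fixtures",
]

#: Canonical order of the 18 amino acids assayed (three-letter codes).
AMINO_ACIDS: tuple[str, ...] = (
    "Arg", "His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val",
    "Ala", "Asp", "Cys", "Glu", "Gly", "Pro", "Ser", "Tyr",
)

#: Proximate / physico-chemical components reported per ingredient lot.
#: DM and all concentrations are air-dry %, GE is MJ/kg, TGS is umol/g.
PROXIMATE_COMPONENTS: tuple[str, ...] = (
    "DM", "GE", "CP", "EE", "Ash", "CF", "NDF", "ADF", "Ca", "TP", "TGS",
)

#: Components carried through the digestibility chain: crude protein + AAs.
COMPONENTS: tuple[str, ...] = ("CP",) + AMINO_ACIDS

_AA_COLUMNS = tuple(a.lower() for a in AMINO_ACIDS)


class SchemaError(ValueError):
    """Header does not match the requested schema (missing/unknown column)."""


class ParseError(ValueError):
    """A cell could not be parsed; carries row and column context."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _positive_pct(name: str, value: float) -> None:
    if not (0.0 < value <= 100.0):
        raise ValidationError(f"{name} must lie in (0, 100], got {value!r}")


@dataclass
class IngredientSample:
    """One ingredient lot: provenance, heating regime and composition.

    ``proximate`` maps the :data:`PROXIMATE_COMPONENTS` keys to air-dry
    concentrations (GE in MJ/kg, TGS in umol/g); ``aa_profile`` maps
    three-letter amino-acid codes to air-dry %.  ``heat_mid_c`` is the
    midpoint of the stated processing-temperature range (a "130 +/- 10 C"
    regime is stored as midpoint 130, half-range 10) and ``heat_minutes``
    the midpoint of the stated duration.
    """

    sample_id: str
    color: str
    heat_mid_c: float
    heat_minutes: float
    origin: str
    proximate: dict[str, float]
    aa_profile: dict[str, float]
    heat_halfrange_c: float = 0.0

    def __post_init__(self) -> None:
        if self.heat_mid_c <= 0:
            raise ValidationError(
                f"{self.sample_id}: heating temperature midpoint must be > 0"
            )
        dm = self.proximate.get("DM")
        if dm is None:
            raise ValidationError(f"{self.sample_id}: DM is mandatory")
        _positive_pct(f"{self.sample_id}: DM", dm)
        for key, val in {**self.proximate, **self.aa_profile}.items():
            if val < 0:
                raise ValidationError(
                    f"{self.sample_id}: {key} concentration must be >= 0, got {val}"
                )
        cp = self.proximate.get("CP")
        if cp is not None and cp >= dm:
            raise ValidationError(f"{self.sample_id}: CP ({cp}) must be < DM ({dm})")
        for aa, val in self.aa_profile.items():
            if val >= dm:
                raise ValidationError(
                    f"{self.sample_id}: {aa} ({val}) must be < DM ({dm})"
                )


@dataclass
class DietAssay:
    """Analyzed composition of one experimental diet (air-dry basis)."""

    diet_id: str
    dm_pct: float
    cp_pct: float
    aa_pct: dict[str, float]
    marker_pct: float = 0.30

    def __post_init__(self) -> None:
        _positive_pct(f"{self.diet_id}: DM", self.dm_pct)
        if self.marker_pct <= 0:
            raise ValidationError(f"{self.diet_id}: marker inclusion must be > 0")
        if self.cp_pct < 0:
            raise ValidationError(f"{self.diet_id}: CP must be >= 0")
        for aa, val in self.aa_pct.items():
            if val < 0:
                raise ValidationError(f"{self.diet_id}: {aa} must be >= 0")

    def component_pct(self, component: str) -> float:
        """Air-dry % of ``component`` (``"CP"`` or an amino-acid code)."""
        if component == "CP":
            return self.cp_pct
        try:
            return self.aa_pct[component]
        except KeyError:
            raise KeyError(
                f"diet {self.diet_id} has no assayed value for {component}"
            ) from None


@dataclass
class DigestaObservation:
    """One pig-period ileal digesta assay, concentrations in g/kg DM."""

    pig_id: str
    period: int
    diet_id: str
    conc_dm: dict[str, float]
    marker_dm: float

    def __post_init__(self) -> None:
        if self.marker_dm <= 0:
            raise ValidationError(
                f"{self.pig_id}/p{self.period}: marker concentration must be > 0"
            )
        if not 1 <= int(self.period) <= 3:
            raise ValidationError(f"{self.pig_id}: period must be 1-3")
        for key, val in self.conc_dm.items():
            if val < 0:
                raise ValidationError(
                    f"{self.pig_id}/p{self.period}: {key} must be >= 0"
                )


@dataclass
class EndogenousLosses:
    """Basal ileal endogenous losses, g per kg dry-matter intake."""

    losses: dict[str, float]

    def __post_init__(self) -> None:
        for key, val in self.losses.items():
            if val < 0:
                raise ValidationError(f"endogenous loss {key} must be >= 0")

    def __getitem__(self, component: str) -> float:
        return self.losses[component]

    def __contains__(self, component: str) -> bool:
        return component in self.losses

    def items(self):
        return self.losses.items()


# ---------------------------------------------------------------------------
# CSV schemas

_INGREDIENT_COLUMNS = (
    "sample_id", "color", "heat_mid_c", "heat_min", "origin",
    "dm", "ge_mj_kg", "cp", "ee", "ash", "cf", "ndf", "adf", "ca", "tp",
    "tgs_umol_g", *_AA_COLUMNS,
)
_INGREDIENT_OPTIONAL = ("heat_halfrange_c",)
_PROXIMATE_FROM_COLUMN = {
    "dm": "DM", "ge_mj_kg": "GE", "cp": "CP", "ee": "EE", "ash": "Ash",
    "cf": "CF", "ndf": "NDF", "adf": "ADF", "ca": "Ca", "tp": "TP",
    "tgs_umol_g": "TGS",
}
_DIET_COLUMNS = ("diet_id", "dm_pct", "cp_pct", "marker_pct", *_AA_COLUMNS)
_DIGESTA_COLUMNS = ("pig_id", "period", "diet_id", "marker_g_kg_dm",
                    "cp", *_AA_COLUMNS)
_ENDOGENOUS_COLUMNS = ("component", "g_kg_dmi")

_SCHEMAS = {
    "ingredients": _INGREDIENT_COLUMNS,
    "diets": _DIET_COLUMNS,
    "digesta": _DIGESTA_COLUMNS,
    "endogenous": _ENDOGENOUS_COLUMNS,
}


def _parse_float(raw: str, row: int, column: str) -> float | None:
    text = raw.strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None
    if math.isnan(value):
        return None
    return value


def _require(value: float | None, row: int, column: str) -> float:
    if value is None:
        raise ParseError(f"row {row}, column {column!r}: value is mandatory")
    return value


def _check_header(header: Sequence[str], schema_name: str) -> None:
    expected = _SCHEMAS[schema_name]
    optional = _INGREDIENT_OPTIONAL if schema_name == "ingredients" else ()
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(
            f"{schema_name} table is missing column(s): {', '.join(missing)}"
        )
    unknown = [c for c in header if c not in expected and c not in optional]
    if unknown:
        raise SchemaError(
            f"{schema_name} table has unknown column(s): {', '.join(unknown)}"
        )


def read_table(path: str | Path, schema_name: str):
    """Read and validate one of the package's CSV tables.

    Parameters
    ----------
    path:
        CSV file location.
    schema_name:
        ``"ingredients"``, ``"diets"``, ``"digesta"`` or ``"endogenous"``.

    Returns
    -------
    list of records for the first three schemas (row order preserved),
    a single :class:`EndogenousLosses` for ``"endogenous"``.
    """
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        _check_header(reader.fieldnames, schema_name)
        rows = list(reader)

    if schema_name == "ingredients":
        return [_ingredient_from_row(row, i + 2) for i, row in enumerate(rows)]
    if schema_name == "diets":
        return [_diet_from_row(row, i + 2) for i, row in enumerate(rows)]
    if schema_name == "digesta":
        return [_digesta_from_row(row, i + 2) for i, row in enumerate(rows)]
    losses: dict[str, float] = {}
    for i, row in enumerate(rows):
        comp = row["component"].strip()
        losses[comp] = _require(
            _parse_float(row["g_kg_dmi"], i + 2, "g_kg_dmi"), i + 2, "g_kg_dmi"
        )
    return EndogenousLosses(losses)


def _ingredient_from_row(row: Mapping[str, str], line: int) -> IngredientSample:
    proximate = {}
    for col, comp in _PROXIMATE_FROM_COLUMN.items():
        val = _parse_float(row[col], line, col)
        if val is not None:
            proximate[comp] = val
    aa = {}
    for col, comp in zip(_AA_COLUMNS, AMINO_ACIDS):
        val = _parse_float(row[col], line, col)
        if val is not None:
            aa[comp] = val
    halfrange = 0.0
    if "heat_halfrange_c" in row and row["heat_halfrange_c"] is not None:
        halfrange = _parse_float(row["heat_halfrange_c"], line,
                                 "heat_halfrange_c") or 0.0
    return IngredientSample(
        sample_id=row["sample_id"].strip(),
        color=row["color"].strip(),
        heat_mid_c=_require(_parse_float(row["heat_mid_c"], line, "heat_mid_c"),
                            line, "heat_mid_c"),
        heat_minutes=_require(_parse_float(row["heat_min"], line, "heat_min"),
                              line, "heat_min"),
        origin=row["origin"].strip(),
        proximate=proximate,
        aa_profile=aa,
        heat_halfrange_c=halfrange,
    )


def _diet_from_row(row: Mapping[str, str], line: int) -> DietAssay:
    aa = {}
    for col, comp in zip(_AA_COLUMNS, AMINO_ACIDS):
        val = _parse_float(row[col], line, col)
        if val is not None:
            aa[comp] = val
    return DietAssay(
        diet_id=row["diet_id"].strip(),
        dm_pct=_require(_parse_float(row["dm_pct"], line, "dm_pct"), line, "dm_pct"),
        cp_pct=_require(_parse_float(row["cp_pct"], line, "cp_pct"), line, "cp_pct"),
        marker_pct=_require(_parse_float(row["marker_pct"], line, "marker_pct"),
                            line, "marker_pct"),
        aa_pct=aa,
    )


def _digesta_from_row(row: Mapping[str, str], line: int) -> DigestaObservation:
    conc = {}
    cp = _parse_float(row["cp"], line, "cp")
    if cp is not None:
        conc["CP"] = cp
    for col, comp in zip(_AA_COLUMNS, AMINO_ACIDS):
        val = _parse_float(row[col], line, col)
        if val is not None:
            conc[comp] = val
    period_raw = row["period"].strip()
    try:
        period = int(period_raw)
    except ValueError:
        raise ParseError(
            f"row {line}, column 'period': cannot parse {period_raw!r} as int"
        ) from None
    return DigestaObservation(
        pig_id=row["pig_id"].strip(),
        period=period,
        diet_id=row["diet_id"].strip(),
        conc_dm=conc,
        marker_dm=_require(
            _parse_float(row["marker_g_kg_dm"], line, "marker_g_kg_dm"),
            line, "marker_g_kg_dm"),
    )


def _format(value: float | None) -> str:
    if value is None:
        return ""
    # 17 significant digits: floats survive a write/read round trip exactly
    return format(value, ".17g")


def write_table(records, path: str | Path, schema_name: str) -> None:
    """Write records back to CSV so that :func:`read_table` round-trips."""
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if schema_name == "ingredients":
            header = list(_INGREDIENT_COLUMNS)
            header.insert(3, "heat_halfrange_c")
            writer.writerow(header)
            for rec in records:
                row = [rec.sample_id, rec.color, _format(rec.heat_mid_c),
                       _format(rec.heat_halfrange_c), _format(rec.heat_minutes),
                       rec.origin]
                row += [_format(rec.proximate.get(comp))
                        for comp in _PROXIMATE_FROM_COLUMN.values()]
                row += [_format(rec.aa_profile.get(aa)) for aa in AMINO_ACIDS]
                writer.writerow(row)
        elif schema_name == "diets":
            writer.writerow(_DIET_COLUMNS)
            for rec in records:
                row = [rec.diet_id, _format(rec.dm_pct), _format(rec.cp_pct),
                       _format(rec.marker_pct)]
                row += [_format(rec.aa_pct.get(aa)) for aa in AMINO_ACIDS]
                writer.writerow(row)
        elif schema_name == "digesta":
            writer.writerow(_DIGESTA_COLUMNS)
            for rec in records:
                row = [rec.pig_id, str(rec.period), rec.diet_id,
                       _format(rec.marker_dm), _format(rec.conc_dm.get("CP"))]
                row += [_format(rec.conc_dm.get(aa)) for aa in AMINO_ACIDS]
                writer.writerow(row)
        else:
            writer.writerow(_ENDOGENOUS_COLUMNS)
            for comp, val in records.items():
                writer.writerow([comp, _format(val)])


# ---------------------------------------------------------------------------
# Bundled reference tables


@dataclass
class FixtureBundle:
    """The published summary tables of the ten-lot rapeseed-cake study.

    Attributes
    ----------
    ingredients:
        Ten :class:`IngredientSample` lots (RSC1..RSC10).
    diets:
        Eleven :class:`DietAssay` records keyed by diet id — one test diet
        per lot plus the nitrogen-free diet (``"NFREE"``).
    endogenous:
        Basal endogenous losses measured on the nitrogen-free diet.
    aid, sid:
        Apparent / standardized ileal digestibility summary tables:
        rows are components, columns the ten lots plus ``mean``, ``sem``
        and the printed ``p_value`` string.
    composition_printed:
        The published per-component Mean and CV(%) columns, kept verbatim
        and separate from the per-lot rows (for EE and TGS the printed CV
        is not reproducible from the printed rows; both are retained).
    """

    ingredients: list[IngredientSample]
    diets: dict[str, DietAssay]
    endogenous: EndogenousLosses
    aid: pd.DataFrame
    sid: pd.DataFrame
    composition_printed: pd.DataFrame

    @property
    def test_diet_ids(self) -> list[str]:
        return [d for d in self.diets if d != "NFREE"]


def _data_path(name: str) -> Path:
    return Path(resources.files("feedsid.data").joinpath(name))


def fixtures() -> FixtureBundle:
    """Load the bundled reference dataset."""
    ingredients = read_table(_data_path("ingredients.csv"), "ingredients")
    diets = {d.diet_id: d for d in read_table(_data_path("diets.csv"), "diets")}
    endogenous = read_table(_data_path("endogenous.csv"), "endogenous")
    aid = pd.read_csv(_data_path("aid_table.csv"), index_col="component")
    sid = pd.read_csv(_data_path("sid_table.csv"), index_col="component")
    printed = pd.read_csv(_data_path("composition_printed.csv"),
                          index_col="component")
    return FixtureBundle(
        ingredients=ingredients,
        diets=diets,
        endogenous=endogenous,
        aid=aid,
        sid=sid,
        composition_printed=printed,
    )
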