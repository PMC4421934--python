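"""Abundance tables: the figshare-like TSV layout, sample designs and QC.

The on-disk dialect is fixed: UTF-8, tab-separated, ``.`` decimal separator,
one leading comment line ``#units=<units>``, then a header row
``species<TAB>class<TAB><sample>...`` and one row per lipid species.  Empty
cells are *not detected* (distinct from an explicit ``0``, which is a
detected zero).  The design file is a two-column TSV (``sample_id``,
``group``) with an optional third ``study`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import (
    MolecularSpeciesKey,
    NomenclatureError,
    SpeciesKey,
    parse_any,
)

__all__ = [
    "UNITS",
    "SampleDesign",
    "AbundanceTable",
    "QCReport",
    "TableFormatError",
    "read_design",
    "write_design",
    "read_table",
    "write_table",
    "qc_internal_standards",
]

UNITS = ("raw", "permille_of_class", "permille_of_lipidome")


class TableFormatError(ValueError):
    """Raised for malformed table or design files."""


@dataclass(frozen=True)
class SampleDesign:
    """One sample's identity: id, biological group, originating study."""

    sample_id: str
    group: str
    study: str = ""


@dataclass
class AbundanceTable:
    """Species x samples abundance matrix with class annotation and design.

    ``data`` is indexed by canonical species names (rows) with sample ids as
    columns; NaN encodes *not detected*.  ``species`` maps each row name to
    its parsed key.  ``design`` maps sample id -> group label.
    """

    data: pd.DataFrame
    species: dict[str, SpeciesKey | MolecularSpeciesKey]
    units: str
    design: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise TableFormatError(f"unknown units tag {self.units!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate species rows: {dup}")
        missing_keys = [n for n in self.data.index if n not in self.species]
        if missing_keys:
            raise TableFormatError(f"rows without species keys: {missing_keys}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise TableFormatError("negative abundance values")
        for s in self.data.columns:
            if self.design and s not in self.design:
                raise TableFormatError(f"sample {s!r} missing from design")

    # -- convenience accessors -------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def species_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def classes(self) -> pd.Series:
        """Per-row lipid class code."""
        return pd.Series({n: k.lipid_class for n, k in self.species.items()},
                         name="class").reindex(self.data.index)

    def groups(self) -> list[str]:
        return sorted(set(self.design.values()))

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.design.get(s) == group]

    def subset_species(self, names) -> "AbundanceTable":
        names = [n for n in self.data.index if n in set(names)]
        if not names:
            raise TableFormatError("species subset is empty")
        return AbundanceTable(
            data=self.data.loc[names].copy(),
            species={n: self.species[n] for n in names},
            units=self.units,
            design=dict(self.design),
        )

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        keep = [s for s in self.data.columns if s in set(sample_ids)]
        if not keep:
            raise TableFormatError("sample subset is empty")
        return AbundanceTable(
            data=self.data[keep].copy(),
            species=dict(self.species),
            units=self.units,
            design={s: g for s, g in self.design.items() if s in set(keep)},
        )

    def restrict_groups(self, groups) -> "AbundanceTable":
        keep = [s for s in self.data.columns
                if self.design.get(s) in set(groups)]
        return self.subset_samples(keep)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), dict(self.species),
                              self.units, dict(self.design))


# ---------------------------------------------------------------------------
# design files

def read_design(path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    if "sample_id" not in cols or "group" not in cols:
        raise TableFormatError(
            f"design file {path} must have columns sample_id, group")
    df.columns = cols
    designs = [
        SampleDesign(sample_id=r.sample_id, group=r.group,
                     study=getattr(r, "study", "") or "")
        for r in df.itertuples(index=False)
    ]
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        raise TableFormatError("duplicate sample ids in design")
    return designs


def write_design(designs: list[SampleDesign], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tstudy\n")
        for d in designs:
            fh.write(f"{d.sample_id}\t{d.group}\t{d.study}\n")
    return path


# ---------------------------------------------------------------------------
# abundance tables

def _fmt(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return format(float(v), ".17g")


def read_table(path, design: list[SampleDesign] | dict[str, str] | None = None,
               units: str | None = None) -> AbundanceTable:
    """Read a TSV abundance table.

    ``design`` may be a list of :class:`SampleDesign` or a sample->group
    mapping; when given, every sample column must appear in it.  The units
    tag is taken from the ``#units=`` header line unless overridden.
    """
    path = Path(path)
    header_units = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#units="):
            header_units = first.strip().split("=", 1)[1]
            rest = fh.read()
        else:
            rest = first + fh.read()
    import io

    df = pd.read_csv(io.StringIO(rest), sep="\t", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "species" not in df.columns:
        raise TableFormatError(f"{path}: no 'species' column")
    has_class = "class" in df.columns
    sample_cols = [c for c in df.columns if c not in ("species", "class")]

    if isinstance(design, dict):
        design_map = dict(design)
    elif design is not None:
        design_map = {d.sample_id: d.group for d in design}
    else:
        design_map = {}
    if design_map:
        unknown = [c for c in sample_cols if c not in design_map]
        if unknown:
            raise TableFormatError(
                f"{path}: sample columns absent from design: {unknown}")

    keys: dict[str, SpeciesKey | MolecularSpeciesKey] = {}
    names: list[str] = []
    values = np.full((len(df), len(sample_cols)), np.nan)
    for i in range(len(df)):
        raw_name = df.iloc[i]["species"]
        try:
            key = parse_any(str(raw_name))
        except NomenclatureError as exc:
            raise TableFormatError(
                f"{path}, row {i + 2}: unparseable species "
                f"{raw_name!r}: {exc}") from exc
        name = str(key)
        if has_class:
            declared = df.iloc[i]["class"]
            declared = "" if pd.isna(declared) else str(declared).strip()
            if declared and declared != key.lipid_class:
                raise TableFormatError(
                    f"{path}, row {i + 2}: class column {declared!r} "
                    f"contradicts species name {name!r}")
        if name in keys:
            raise TableFormatError(f"{path}: duplicate species row {name!r}")
        keys[name] = key
        names.append(name)
        for j, col in enumerate(sample_cols):
            cell = df.iloc[i][col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell == "":
                continue
            v = float(cell)
            if v < 0:
                raise TableFormatError(
                    f"{path}, row {i + 2}, sample {col}: negative value {v}")
            values[i, j] = v

    data = pd.DataFrame(values, index=pd.Index(names, name="species"),
                        columns=sample_cols)
    tag = units or header_units or "raw"
    design_for_table = ({s: design_map[s] for s in sample_cols}
                        if design_map else {})
    return AbundanceTable(data=data, species=keys, units=tag,
                          design=design_for_table)


def write_table(table: AbundanceTable, path) -> Path:
    """Write a table in the fixed TSV dialect; round-trips bit-exactly."""
    path = Path(path)
    classes = table.classes
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#units={table.units}\n")
        fh.write("species\tclass\t" + "\t".join(table.samples) + "\n")
        for name in table.data.index:
            row = table.data.loc[name]
            cells = "\t".join(_fmt(row[s]) for s in table.samples)
            fh.write(f"{name}\t{classes[name]}\t{cells}\n")
    return path


# ---------------------------------------------------------------------------
# internal-standard QC

@dataclass
class QCReport:
    """Result of the internal-standard extraction-efficiency check."""

    batch_means: pd.Series                 # per standard
    deviations: pd.DataFrame               # standards x samples, |v-mean|/mean
    rejected: list[str]
    threshold: float

    def passed(self) -> list[str]:
        return [s for s in self.deviations.columns if s not in self.rejected]


def qc_internal_standards(standards_table: AbundanceTable,
                          threshold: float = 0.30) -> QCReport:
    """Reject samples whose internal-standard recovery deviates too far.

    For each standard the batch mean is computed once over all samples
    (the candidate sample included); a sample is rejected when for any
    standard the relative deviation from that mean is strictly greater
    than ``threshold`` (default 30%).  There is no iterative re-meaning
    after rejection.
    """
    if len(standards_table.samples) < 2:
        raise TableFormatError("QC needs at least 2 samples")
    data = standards_table.data
    means = data.mean(axis=1, skipna=True)
    if (means.fillna(0) == 0).any():
        bad = means.index[means.fillna(0) == 0].tolist()
        raise TableFormatError(f"zero batch mean for standard(s): {bad}")
    dev = (data.sub(means, axis=0)).abs().div(means, axis=0)
    rejected = [s for s in data.columns
                if (dev[s].dropna() > threshold).any()]
    return QCReport(batch_means=means, deviations=dev, rejected=rejected,
                    threshold=threshold)
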