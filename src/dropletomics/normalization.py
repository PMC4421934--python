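"""Normalization of raw MS signal tables to relative ‰ profiles.

Two conventions are supported:

* *class-relative*: each species' signal as a per-mille share of the summed
  signal of its lipid class in that sample.  No calibration is needed since
  ionization efficiencies within a class are similar.
* *lipidome-relative*: raw signals are first converted to molar amounts via
  spiked internal standards (one-point calibration against the median molar
  response of a class's standards), then expressed per-mille of the summed
  molar lipidome of the sample.

Missing (not-detected) values never enter a sum and stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nomenclature import parse_any
from .tables_io import AbundanceTable, TableFormatError

__all__ = [
    "InternalStandard",
    "StandardPanel",
    "NormalizationError",
    "class_relative",
    "lipidome_relative",
    "read_standard_panel",
]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class InternalStandard:
    """A spiked non-endogenous lipid of known molar amount."""

    name: str                 # canonical molecular-species name
    lipid_class: str
    amount: float             # spiked molar amount (nmol per sample)

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise NormalizationError(
                f"standard {self.name}: non-positive amount {self.amount}")


@dataclass
class StandardPanel:
    """The set of internal standards available for molar calibration."""

    standards: list[InternalStandard]

    def for_class(self, lipid_class: str) -> list[InternalStandard]:
        return [s for s in self.standards if s.lipid_class == lipid_class]

    def classes(self) -> set[str]:
        return {s.lipid_class for s in self.standards}


def read_standard_panel(path) -> StandardPanel:
    """Read a panel TSV with columns standard_name, class, amount[, unit]."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.lower() for c in df.columns]
    needed = {"standard_name", "class", "amount"}
    if not needed <= set(df.columns):
        raise TableFormatError(f"panel {path} needs columns {sorted(needed)}")
    standards = []
    for _, r in df.iterrows():
        key = parse_any(r["standard_name"])
        standards.append(InternalStandard(name=str(key),
                                          lipid_class=r["class"].strip(),
                                          amount=float(r["amount"])))
    return StandardPanel(standards)


def class_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert raw signals to ‰-of-class profiles.

    Per class and sample, each detected species becomes
    ``1000 * value / sum(values of that class detected in the sample)``.
    Idempotent on already class-normalized input.
    """
    if table.units not in ("raw", "permille_of_class"):
        raise NormalizationError(
            f"class_relative expects raw input, got {table.units}")
    classes = table.classes
    out = table.data.copy()
    for cls in sorted(classes.unique()):
        rows = classes.index[classes == cls]
        block = table.data.loc[rows]
        totals = block.sum(axis=0, skipna=True)
        dead = [s for s in block.columns
                if (totals[s] == 0 or block[s].isna().all())]
        if dead:
            raise NormalizationError(
                f"class {cls}: zero or all-missing total in sample(s) {dead}")
        out.loc[rows] = 1000.0 * block.div(totals, axis=1)
    return AbundanceTable(data=out, species=dict(table.species),
                          units="permille_of_class",
                          design=dict(table.design))


def _molar_factors(standards_table: AbundanceTable, panel: StandardPanel,
                   required_classes) -> pd.DataFrame:
    """Per class and sample, the molar response factor amount/signal.

    With several standards per class the factor is the median of the
    per-standard responses — a one-point robust calibration against the
    class's standard panel.
    """
    factors = {}
    for cls in sorted(required_classes):
        stds = panel.for_class(cls)
        if not stds:
            raise NormalizationError(f"no internal standard for class {cls}")
        per_sample = []
        for s in standards_table.samples:
            responses = []
            for std in stds:
                if std.name not in standards_table.data.index:
                    raise NormalizationError(
                        f"standard {std.name} absent from standards table")
                sig = standards_table.data.loc[std.name, s]
                if pd.isna(sig) or sig == 0:
                    raise NormalizationError(
                        f"standard {std.name}: missing/zero signal "
                        f"in sample {s}")
                responses.append(std.amount / float(sig))
            per_sample.append(float(np.median(responses)))
        factors[cls] = pd.Series(per_sample, index=standards_table.samples)
    return pd.DataFrame(factors).T  # classes x samples


def lipidome_relative(table: AbundanceTable, panel: StandardPanel,
                      standards_table: AbundanceTable) -> AbundanceTable:
    """Convert raw signals to ‰-of-lipidome profiles via internal standards.

    Each class's signals are scaled to molar amounts by that class's
    standard response factor, then every sample is normalized so its summed
    molar lipidome equals 1000 ‰.
    """
    if table.units != "raw":
        raise NormalizationError(
            f"lipidome_relative expects raw input, got {table.units}")
    classes = table.classes
    fac = _molar_factors(standards_table, panel, set(classes.unique()))
    missing_samples = [s for s in table.samples
                       if s not in standards_table.samples]
    if missing_samples:
        raise NormalizationError(
            f"standards table lacks sample(s) {missing_samples}")
    molar = table.data.copy()
    for cls in fac.index:
        rows = classes.index[classes == cls]
        molar.loc[rows] = table.data.loc[rows].mul(
            fac.loc[cls, table.samples], axis=1)
    totals = molar.sum(axis=0, skipna=True)
    if (totals == 0).any():
        raise NormalizationError("zero molar total in a sample")
    out = 1000.0 * molar.div(totals, axis=1)
    return AbundanceTable(data=out, species=dict(table.species),
                          units="permille_of_lipidome",
                          design=dict(table.design))
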