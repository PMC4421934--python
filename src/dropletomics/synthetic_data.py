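"""Synthetic lipid-droplet lipidome generator with known ground truth.

Emulates the statistical structure of hepatocyte lipid-droplet lipidomics
under nutritional and genetic stress: five sample groups (WT-FED, WT-FAS,
WT-HFD, KO-FED, KO-FAS), a TG species grid spanning TG 28:0 to TG 62:15
(>100 species) plus small DG/PC panels, log-normal multiplicative signal
noise, group-specific chain-length/unsaturation trends, planted
discriminatory species with known fold effects, internal-standard rows with
controllable deviation, and a detection floor that turns low-abundance
cells into not-detected entries.

Every random quantity flows from one integer seed through a single
generator stream, so identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nomenclature import SpeciesKey, parse_any
from .tables_io import AbundanceTable, SampleDesign

__all__ = [
    "GridSpec",
    "PlantedEffect",
    "StandardSpec",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "make_species_grid",
    "generate",
    "paperlike_preset",
]


@dataclass(frozen=True)
class GridSpec:
    """Species grid for one class: even carbon range + double-bond caps.

    The double-bond count runs from 0 to ``min(max_db, (carbons -
    db_onset) // 2)`` — longer chains admit more unsaturation, mirroring
    the elongation/desaturation coupling of fatty-acid metabolism.
    """

    lipid_class: str = "TG"
    carbon_range: tuple[int, int] = (28, 62)
    max_db: int = 15
    db_onset: int = 32

    def caps(self, carbons: int) -> int:
        return max(0, min(self.max_db, (carbons - self.db_onset) // 2))


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative abundance effect of one species in one group."""

    species: str
    group: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"effect fold must be > 0, got {self.fold}")


@dataclass(frozen=True)
class StandardSpec:
    """An internal-standard row: molecular species, class, spiked amount."""

    name: str
    lipid_class: str
    amount: float


@dataclass
class GeneratorConfig:
    """Everything the generator needs; the defaults are the study layout.

    * ``groups``: (label, n animals) pairs;
    * ``grids``: one :class:`GridSpec` per lipid class;
    * ``sigma``: log-scale s.d. of the multiplicative species noise;
    * ``sample_sigma``: log-scale s.d. of the per-sample instrument
      response (cancels under class-relative normalization);
    * ``chain_shift`` / ``unsat_shift``: per-group log-abundance slopes in
      (carbons - 52) and (double_bonds - 3), producing the global
      chain-length / unsaturation trends of the stress phenotypes;
    * ``planted``: explicit per-species fold effects (the ground truth
      discriminators);
    * ``standards``: internal-standard rows appended to the raw table;
      ``standard_sigma`` controls their relative deviation and
      ``standard_outliers`` maps sample id -> deviation factor for QC
      test scenarios;
    * ``detection_floor``: class-relative ‰ below which a cell becomes
      not-detected.
    """

    seed: int = 1
    groups: list[tuple[str, int]] = field(default_factory=lambda: [
        ("WT-FED", 3), ("WT-FAS", 3), ("WT-HFD", 6),
        ("KO-FED", 3), ("KO-FAS", 3)])
    grids: dict[str, GridSpec] = field(default_factory=lambda: {
        "TG": GridSpec("TG", (28, 62), 15, 32),
        "DG": GridSpec("DG", (30, 40), 4, 30),
        "PC": GridSpec("PC", (30, 40), 6, 28),
    })
    sigma: float = 0.25
    sample_sigma: float = 0.10
    chain_shift: dict[str, float] = field(default_factory=dict)
    unsat_shift: dict[str, float] = field(default_factory=dict)
    planted: list[PlantedEffect] = field(default_factory=list)
    standards: list[StandardSpec] = field(default_factory=lambda: [
        StandardSpec("TG 17:0/17:0/17:0", "TG", 40.0),
        StandardSpec("PC 12:0/12:0", "PC", 1.2),
    ])
    standard_sigma: float = 0.05
    standard_outliers: dict[str, float] = field(default_factory=dict)
    detection_floor: float = 0.2
    raw_scale: float = 1e6


def make_species_grid(spec: GridSpec) -> list[SpeciesKey]:
    """Even-carbon species grid, sorted by (carbons, double bonds)."""
    lo, hi = spec.carbon_range
    if lo > hi:
        raise ValueError(f"empty carbon range {spec.carbon_range}")
    start = lo if lo % 2 == 0 else lo + 1
    grid = [SpeciesKey(spec.lipid_class, c, db)
            for c in range(start, hi + 1, 2)
            for db in range(0, spec.caps(c) + 1)]
    if not grid:
        raise ValueError(f"grid spec {spec} yields no species")
    return grid


def _baseline(keys: list[SpeciesKey]) -> np.ndarray:
    """Smooth hump over (carbons, double bonds), peaking near 52:2-52:3.

    The shape mimics a hepatocyte LD TG profile: abundance concentrated at
    C50-C56 with low-to-moderate unsaturation, decaying toward the short
    saturated and very-long polyunsaturated edges.
    """
    c = np.array([k.carbons for k in keys], dtype=float)
    db = np.array([k.double_bonds for k in keys], dtype=float)
    c_mid = 52.0
    db_mode = np.clip(0.30 * (c - 44.0), 0.0, None)
    w = np.exp(-0.5 * ((c - c_mid) / 4.0) ** 2
               - 0.5 * ((db - db_mode) / 1.8) ** 2)
    return w / w.sum() * 1000.0          # noiseless ‰-of-class profile


def _group_factor(keys: list[SpeciesKey], group: str,
                  config: GeneratorConfig) -> np.ndarray:
    c = np.array([k.carbons for k in keys], dtype=float)
    db = np.array([k.double_bonds for k in keys], dtype=float)
    f = np.exp(config.chain_shift.get(group, 0.0) * (c - 52.0)
               + config.unsat_shift.get(group, 0.0) * (db - 3.0))
    names = [str(k) for k in keys]
    for eff in config.planted:
        if eff.group == group and eff.species in names:
            f[names.index(eff.species)] *= eff.fold
    return f


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream recovery tests."""

    planted: list[PlantedEffect]
    noiseless_profiles: dict[str, pd.DataFrame]
    # ^ class -> species x groups noiseless ‰-of-class profiles
    standard_names: list[str]
    seed: int

    def discriminators(self, group_a: str, group_b: str) -> dict[str, int]:
        """Planted species differing between two groups; +1 means higher
        in ``group_a``, -1 higher in ``group_b``."""
        folds_a = {e.species: e.fold for e in self.planted
                   if e.group == group_a}
        folds_b = {e.species: e.fold for e in self.planted
                   if e.group == group_b}
        out = {}
        for sp in set(folds_a) | set(folds_b):
            ratio = folds_a.get(sp, 1.0) / folds_b.get(sp, 1.0)
            if not math.isclose(ratio, 1.0):
                out[sp] = 1 if ratio > 1 else -1
        return out

    def base_peak(self, lipid_class: str) -> str:
        prof = self.noiseless_profiles[lipid_class]
        return str(prof.mean(axis=1).idxmax())

    def average_cl_db(self, lipid_class: str,
                      group: str) -> tuple[float, float]:
        from .profiling import average_cl_db
        prof = self.noiseless_profiles[lipid_class][group]
        return average_cl_db(prof)


@dataclass
class SyntheticDataset:
    """A generated raw table (standards appended) plus its ground truth."""

    table: AbundanceTable            # endogenous + internal-standard rows
    truth: GroundTruth
    design: list[SampleDesign]

    @property
    def standards(self) -> AbundanceTable:
        return self.table.subset_species(self.truth.standard_names)

    @property
    def endogenous(self) -> AbundanceTable:
        keep = [n for n in self.table.species_names
                if n not in set(self.truth.standard_names)]
        return self.table.subset_species(keep)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one raw abundance table under the configured group structure.

    Per sample: ``signal(i) = baseline(i) * group_factor(i) * exp(N(0,
    sigma)) * sample_response``, with cells whose class-relative share
    falls below the detection floor turned into not-detected.  Internal-
    standard rows get ``amount * response * exp(N(0, standard_sigma))``
    times any configured per-sample outlier factor.
    """
    if config.sigma < 0 or config.sample_sigma < 0:
        raise ValueError("noise sigmas must be >= 0")
    rng = np.random.default_rng(config.seed)
    design = [SampleDesign(f"{g}-{i + 1}", g)
              for g, n in config.groups for i in range(n)]
    samples = [d.sample_id for d in design]
    design_map = {d.sample_id: d.group for d in design}

    all_names: list[str] = []
    species_map: dict[str, object] = {}
    blocks: list[np.ndarray] = []
    noiseless: dict[str, pd.DataFrame] = {}
    groups = [g for g, _ in config.groups]

    sample_response = config.raw_scale * np.exp(
        rng.normal(0.0, config.sample_sigma, size=len(samples))
    ) if config.sample_sigma > 0 else np.full(len(samples), config.raw_scale)

    for cls in sorted(config.grids):
        keys = make_species_grid(config.grids[cls])
        names = [str(k) for k in keys]
        base = _baseline(keys)
        factors = {g: _group_factor(keys, g, config) for g in groups}
        # noiseless class-relative expectation per group
        prof = {}
        for g in groups:
            v = base * factors[g]
            prof[g] = 1000.0 * v / v.sum()
        noiseless[cls] = pd.DataFrame(prof, index=names)
        block = np.empty((len(keys), len(samples)))
        for j, s in enumerate(samples):
            mean_vec = base * factors[design_map[s]]
            noise = (np.exp(rng.normal(0.0, config.sigma, size=len(keys)))
                     if config.sigma > 0 else 1.0)
            block[:, j] = mean_vec * noise * sample_response[j]
        # detection floor on the class-relative share
        shares = 1000.0 * block / block.sum(axis=0, keepdims=True)
        block[shares < config.detection_floor] = np.nan
        blocks.append(block)
        all_names.extend(names)
        species_map.update(dict(zip(names, keys)))

    # internal-standard rows
    std_names = []
    std_rows = []
    for std in config.standards:
        key = parse_any(std.name)
        name = str(key)
        std_names.append(name)
        species_map[name] = key
        noise = (np.exp(rng.normal(0.0, config.standard_sigma,
                                   size=len(samples)))
                 if config.standard_sigma > 0 else np.ones(len(samples)))
        outlier = np.array([config.standard_outliers.get(s, 1.0)
                            for s in samples])
        std_rows.append(std.amount * sample_response * noise * outlier)
    all_names.extend(std_names)
    values = np.vstack(blocks + ([np.vstack(std_rows)] if std_rows else []))

    data = pd.DataFrame(values, index=pd.Index(all_names, name="species"),
                        columns=samples)
    table = AbundanceTable(data=data, species=species_map, units="raw",
                           design=design_map)
    truth = GroundTruth(planted=list(config.planted),
                        noiseless_profiles=noiseless,
                        standard_names=std_names, seed=config.seed)
    return SyntheticDataset(table=table, truth=truth, design=design)


# ---------------------------------------------------------------------------
# the study-like preset

#: Fasting remodels the abundant TG pool toward polyunsaturated species and
#: away from near-saturated ones; fold magnitudes sit inside the 0.2-5x
#: band the stress phenotypes display.
_FASTING_EFFECTS = [
    ("TG 52:4", 2.0), ("TG 52:5", 2.5), ("TG 54:5", 2.0), ("TG 54:6", 2.5),
    ("TG 56:7", 2.5), ("TG 56:8", 3.0), ("TG 52:1", 0.5), ("TG 54:2", 0.5),
]
#: High-fat diet enriches long near-saturated TG.
_HFD_EFFECTS = [
    ("TG 52:1", 3.0), ("TG 54:1", 3.0), ("TG 54:2", 2.5), ("TG 56:2", 2.5),
]
#: Combined genetic + fasting stress enriches very-long polyunsaturated TG.
_SUPERSTRESS_EFFECTS = [
    ("TG 60:7", 4.0), ("TG 60:9", 4.0), ("TG 62:10", 4.0), ("TG 62:12", 4.0),
]


def paperlike_preset(seed: int = 1,
                     n_per_group: int | None = None) -> GeneratorConfig:
    """Five-group study layout with documented planted discriminators.

    Default group sizes are the study's (n=3 for the genetic-stress arm,
    n=6 for the diet arm); ``n_per_group`` overrides all of them, which the
    recovery tests use at n=10.  Planted effects: fasting shifts (both FAS
    groups), high-fat-diet markers (WT-HFD), and super-stress enrichment of
    very long polyunsaturated TG (KO-FAS), plus mild global
    chain/unsaturation trends for the KO background.
    """
    groups = [("WT-FED", 3), ("WT-FAS", 3), ("WT-HFD", 6),
              ("KO-FED", 3), ("KO-FAS", 3)]
    if n_per_group is not None:
        groups = [(g, n_per_group) for g, _ in groups]
    planted = []
    for sp, fold in _FASTING_EFFECTS:
        planted.append(PlantedEffect(sp, "WT-FAS", fold))
        planted.append(PlantedEffect(sp, "KO-FAS", fold))
    planted += [PlantedEffect(sp, "WT-HFD", fold) for sp, fold in _HFD_EFFECTS]
    planted += [PlantedEffect(sp, "KO-FAS", fold)
                for sp, fold in _SUPERSTRESS_EFFECTS]
    return GeneratorConfig(
        seed=seed,
        groups=groups,
        planted=planted,
        chain_shift={"WT-HFD": 0.02, "KO-FED": 0.015, "KO-FAS": 0.015},
        unsat_shift={"WT-HFD": -0.04, "WT-FAS": 0.05, "KO-FAS": 0.05,
                     "KO-FED": -0.02},
    )


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Same conditions, different random stream."""
    return replace(config, seed=seed)
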