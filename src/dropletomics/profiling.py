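"""Group-level descriptive statistics for lipid-species profiles.

Covers the per-group mean/s.d. profiles, fold-change heat-map matrices
(clipped to [0.2, 5], grey = not detected), tiered pooled-variance t tests,
base-peak species selection and abundance-weighted averaging of chain
lengths and double-bond counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import SpeciesKey, parse_species
from .tables_io import AbundanceTable

__all__ = [
    "GroupProfile",
    "HeatmapMatrix",
    "AveragingResult",
    "ProfilingError",
    "group_profiles",
    "mean_of_group_means",
    "fold_change_heatmap",
    "t_test_tiers",
    "select_by_base_peak",
    "average_cl_db",
    "average_cl_db_by_group",
    "TIERS",
]

TIERS = (0.05, 0.01, 0.001)


class ProfilingError(ValueError):
    pass


@dataclass
class GroupProfile:
    """Mean +/- s.d. profile of one sample group.

    ``n`` counts the animals in the group; the s.d. uses the n-1
    denominator and is absent (None) for single-animal groups.  Species not
    detected in any sample of the group have a missing (NaN) mean.
    """

    group: str
    n: int
    mean: pd.Series
    sd: pd.Series | None


def group_profiles(table: AbundanceTable,
                   design: dict[str, str] | None = None) -> list[GroupProfile]:
    """Per-group arithmetic mean and sample s.d. for every species.

    Means/s.d. are computed over the samples where a species was detected;
    a species missing in every sample of a group gets a missing mean.
    """
    design = design or table.design
    if not design:
        raise ProfilingError("no sample design available")
    groups = sorted(set(design.values()))
    out = []
    for g in groups:
        cols = [s for s in table.samples if design.get(s) == g]
        if not cols:
            raise ProfilingError(f"group {g} has zero samples")
        block = table.data[cols]
        mean = block.mean(axis=1, skipna=True)
        sd = block.std(axis=1, ddof=1, skipna=True) if len(cols) >= 2 else None
        out.append(GroupProfile(group=g, n=len(cols), mean=mean, sd=sd))
    return out


def mean_of_group_means(profiles: list[GroupProfile]) -> pd.Series:
    """Across-group mean of the group mean profiles (detected groups only)."""
    means = pd.concat([p.mean for p in profiles], axis=1,
                      keys=[p.group for p in profiles])
    return means.mean(axis=1, skipna=True)


@dataclass
class HeatmapMatrix:
    """Species x groups fold changes against the across-group mean.

    Finite entries are clipped to [lo, hi]; NaN marks species not detected
    in that group (rendered grey).
    """

    folds: pd.DataFrame
    lo: float = 0.2
    hi: float = 5.0
    unclipped: pd.DataFrame | None = field(default=None, repr=False)


def fold_change_heatmap(profiles: list[GroupProfile], lo: float = 0.2,
                        hi: float = 5.0) -> HeatmapMatrix:
    """Fold change of each group mean versus the across-group mean.

    The reference for a species is the arithmetic mean of its group means
    over the groups where it was detected; folds are clipped to [lo, hi].
    A fold of exactly 1 means no change (rendered black).
    """
    if len(profiles) < 2:
        raise ProfilingError("need at least 2 groups for fold changes")
    means = pd.concat([p.mean for p in profiles], axis=1,
                      keys=[p.group for p in profiles])
    ref = means.mean(axis=1, skipna=True)
    detected_somewhere = means.notna().any(axis=1)
    zero_ref = detected_somewhere & (ref == 0)
    if zero_ref.any():
        raise ProfilingError(
            f"zero reference for detected species: "
            f"{means.index[zero_ref].tolist()}")
    raw = means.div(ref, axis=0)
    return HeatmapMatrix(folds=raw.clip(lower=lo, upper=hi), lo=lo, hi=hi,
                         unclipped=raw)


def t_test_tiers(group_a, group_b) -> tuple[float, float, str]:
    """Two-sided pooled-variance (equal-variance) two-sample t test.

    Returns ``(t, p, tier)`` with tier in {'ns', '0.05', '0.01', '0.001'},
    the smallest listed significance level the p value falls under.
    Degenerate zero-variance inputs: equal means give (0, 1, 'ns'),
    unequal means are reported as maximally significant (p = 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ProfilingError("t test needs >= 2 values per group")
    na, nb = a.size, b.size
    sa2 = a.var(ddof=1)
    sb2 = b.var(ddof=1)
    pooled = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, "ns"
        return math.copysign(math.inf, diff), 0.0, "0.001"
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return t, p, _tier(p)


def _tier(p: float) -> str:
    tier = "ns"
    for level in TIERS:
        if p < level:
            tier = format(level, "g")
    return tier


def select_by_base_peak(mean_profile: pd.Series,
                        threshold: float) -> list[str]:
    """Species at or above ``threshold`` x the class base peak.

    ``mean_profile`` must be restricted to one lipid class; the base peak
    is the species of highest abundance (set to 100%).  The comparison is
    inclusive ("threshold and above").  Returns names in profile order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ProfilingError(f"threshold {threshold} outside (0, 1]")
    prof = mean_profile.dropna()
    if prof.empty:
        raise ProfilingError("empty profile")
    base = prof.max()
    if base <= 0:
        raise ProfilingError("base peak abundance is zero")
    keep = prof[prof >= threshold * base]
    return list(keep.index)


def _keys(index, species_map=None) -> list[SpeciesKey]:
    keys = []
    for name in index:
        if species_map and name in species_map:
            k = species_map[name]
            if not isinstance(k, SpeciesKey):
                from .nomenclature import species_of
                k = species_of(k)
        else:
            k = parse_species(name)
        keys.append(k)
    return keys


def average_cl_db(profile: pd.Series, subset=None,
                  species_map=None) -> tuple[float, float]:
    """Abundance-weighted mean chain length and double-bond count.

    ``mean_cl = sum_i a_i * carbons_i / sum_i a_i`` over the subset (all
    species of the profile when ``subset`` is None), and analogously for
    double bonds.  Invariant to uniform rescaling of the abundances; weights
    are renormalized over the subset, so partial profiles are comparable.
    """
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ProfilingError("empty species subset")
        profile = profile.reindex(subset)
    weights = profile.fillna(0.0).to_numpy(dtype=float)
    if weights.sum() <= 0:
        raise ProfilingError("all-zero abundances in subset")
    keys = _keys(profile.index, species_map)
    carbons = np.array([k.carbons for k in keys], dtype=float)
    dbs = np.array([k.double_bonds for k in keys], dtype=float)
    total = weights.sum()
    return (float(weights @ carbons / total), float(weights @ dbs / total))


@dataclass
class AveragingResult:
    """Per-group weighted chain-length / double-bond averages.

    ``cl``/``db`` are per-group means over animals; ``cl_sd``/``db_sd`` the
    corresponding sample s.d. (NaN for single-animal groups).  ``selected``
    records the species subset used and ``threshold`` the base-peak
    fraction that produced it.
    """

    cl: pd.Series
    db: pd.Series
    cl_sd: pd.Series
    db_sd: pd.Series
    n: pd.Series
    selected: list[str]
    threshold: float | None


def average_cl_db_by_group(table: AbundanceTable, subset,
                           design: dict[str, str] | None = None,
                           threshold: float | None = None) -> AveragingResult:
    """Weighted cl/db averages computed per animal, then summarized per group.

    This is the per-animal path: the statistic is computed for each sample
    and averaged within group (mean +/- s.d., n = animals).
    """
    design = design or table.design
    if not design:
        raise ProfilingError("no sample design available")
    subset = list(subset)
    stats_rows = {}
    for s in table.samples:
        prof = table.data[s]
        cl, db = average_cl_db(prof, subset, species_map=table.species)
        stats_rows[s] = (design.get(s), cl, db)
    df = pd.DataFrame.from_dict(stats_rows, orient="index",
                                columns=["group", "cl", "db"])
    grouped = df.groupby("group")
    return AveragingResult(
        cl=grouped["cl"].mean(), db=grouped["db"].mean(),
        cl_sd=grouped["cl"].std(ddof=1), db_sd=grouped["db"].std(ddof=1),
        n=grouped["cl"].size(), selected=subset, threshold=threshold,
    )
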