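"""Two-class O-PLS-DA with S-plot statistics and discriminant selection.

Orthogonal projections to latent structures discriminant analysis removes
from the data matrix the variation orthogonal to the class contrast before
extracting a single predictive component, so that between-group variance is
concentrated in the first (predictive) dimension.

Algorithm (single response y coded +1/-1, X preprocessed):

1. ``w = X'y / ||X'y||`` — the predictive weight;
2. for each orthogonal round: ``t = Xw``; ``p = X't/(t't)``;
   ``w_o = p - (w'p)w`` normalized; ``t_o = X w_o``;
   ``p_o = X't_o/(t_o't_o)``; ``X <- X - t_o p_o'``;
3. predictive score ``t = X_filtered w`` and loading
   ``p = X_filtered' t / (t't)``.

The S-plot pairs each species' covariance with the predictive score
(``cov(t, x_i)``, the model loading on the original variable scale) with
its Pearson correlation to the score; species at the extremes of both axes
are discriminant candidates.  The *weighted loading* used for selection is
``p_i * |corr(t, x_i)|`` (a package convention, configurable by combining
the exposed pieces differently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable
from .pca_phenotyping import fit_pca

__all__ = [
    "OplsModel",
    "SPlotSelection",
    "OplsError",
    "fit_opls_da",
    "s_plot",
    "weighted_loadings",
    "select_discriminants",
    "evaluate_subsets",
]


class OplsError(ValueError):
    pass


@dataclass
class OplsModel:
    """A fitted two-class O-PLS model.

    Scores/weights refer to the preprocessed matrix (mean-centered, and by
    default unit-variance scaled).  ``corr``/``cov`` relate the predictive
    score to the *unfiltered* preprocessed variables — the S-plot axes.
    """

    species: list[str]
    samples: list[str]
    center: np.ndarray
    scale: np.ndarray | None
    w: np.ndarray                      # predictive weight, unit norm
    t: np.ndarray                      # predictive score
    p: np.ndarray                      # predictive loading
    orthogonal: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    # ^ per round (w_o, t_o, p_o)
    y: pd.Series                       # +1/-1 coding per sample
    positive_group: str
    negative_group: str
    corr: pd.Series = field(repr=False, default=None)
    cov: pd.Series = field(repr=False, default=None)

    @property
    def n_orthogonal(self) -> int:
        return len(self.orthogonal)


def _preprocess(table: AbundanceTable, groups: tuple[str, str],
                scale: str) -> tuple[np.ndarray, pd.Series, list[str],
                                     np.ndarray, np.ndarray | None]:
    sub = table.restrict_groups(groups)
    labels = {s: sub.design[s] for s in sub.samples}
    present = sorted(set(labels.values()))
    if len(present) != 2:
        raise OplsError(f"need exactly 2 groups with samples, got {present}")
    for g in present:
        if sum(1 for v in labels.values() if v == g) < 2:
            raise OplsError(f"group {g} has fewer than 2 samples")
    pos, neg = present[0], present[1]   # alphabetically first coded +1
    y = pd.Series({s: (1.0 if labels[s] == pos else -1.0)
                   for s in sub.samples})
    X = sub.data.T.reindex(sub.samples).to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    center = X.mean(axis=0)
    Xc = X - center
    scale_vec = None
    if scale == "uv":
        scale_vec = X.std(axis=0, ddof=1)
        # constant species carry no class information; leave them centered
        # (all-zero) rather than dividing by a zero s.d. — they surface in
        # the S-plot with a missing correlation
        scale_vec = np.where(scale_vec == 0, 1.0, scale_vec)
        Xc = Xc / scale_vec
        if not np.any(Xc.std(axis=0) > 0):
            raise OplsError("zero-variance X after preprocessing")
    elif scale != "center":
        raise OplsError(f"unknown preprocessing {scale!r}")
    return Xc, y, list(sub.data.index), center, scale_vec


def fit_opls_da(table: AbundanceTable, groups: tuple[str, str],
                n_orthogonal: int = 1, scale: str = "uv") -> OplsModel:
    """Fit single-response O-PLS-DA between two sample groups.

    ``groups`` names the two classes (order irrelevant; the alphabetically
    first is coded +1).  ``n_orthogonal`` orthogonal components are removed
    before the predictive component is extracted; 0 gives plain
    single-component PLS.  ``scale`` is ``"uv"`` (center + unit variance,
    default) or ``"center"``.
    """
    if n_orthogonal < 0:
        raise OplsError("n_orthogonal must be >= 0")
    X0, y, species, center, scale_vec = _preprocess(table, tuple(groups),
                                                    scale)
    yv = y.to_numpy()
    w = X0.T @ yv
    norm = np.linalg.norm(w)
    if norm == 0:
        raise OplsError("X'y is zero: no class-correlated variation")
    w = w / norm
    X = X0.copy()
    orthogonal = []
    for _ in range(n_orthogonal):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break                     # nothing orthogonal left to remove
        w_o = w_o / n_wo
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        orthogonal.append((w_o, t_o, p_o))
    t = X @ w
    if np.allclose(t, 0):
        raise OplsError("degenerate predictive score (zero variance)")
    p = X.T @ t / (t @ t)
    n = X0.shape[0]
    cov = pd.Series(X0.T @ (t - t.mean()) / (n - 1), index=species)
    sd_x = X0.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_vals = np.where(sd_x > 0, cov.to_numpy() / (sd_x * sd_t),
                             np.nan)
    corr = pd.Series(corr_vals, index=species)
    pos, neg = sorted(set(table.design[s] for s in y.index))
    return OplsModel(species=species, samples=list(y.index), center=center,
                     scale=scale_vec, w=w, t=t, p=p, orthogonal=orthogonal,
                     y=y, positive_group=pos, negative_group=neg,
                     corr=corr, cov=cov)


def s_plot(model: OplsModel) -> pd.DataFrame:
    """S-plot coordinates: loading axis (cov with score) vs correlation.

    Species with zero variance get a missing correlation.
    """
    return pd.DataFrame({"loading": model.cov, "correlation": model.corr})


def weighted_loadings(model: OplsModel) -> pd.Series:
    """Predictive loading weighted by |correlation to the score|."""
    p = pd.Series(model.p, index=model.species)
    return p * model.corr.abs().fillna(0.0)


@dataclass
class SPlotSelection:
    """Discriminant species split by the sign of their score correlation."""

    positive: list[str]
    negative: list[str]
    corr_threshold: float
    loading_quantile: float

    @property
    def union(self) -> list[str]:
        return self.positive + self.negative


def select_discriminants(model: OplsModel, corr_threshold: float = 0.8,
                         loading_quantile: float = 0.9) -> SPlotSelection:
    """Pick S-plot extremes: strong correlation and large weighted loading.

    A species enters the positive (resp. negative) subset when its
    correlation to the predictive score is >= +``corr_threshold`` (resp.
    <= -threshold) and its |weighted loading| reaches the
    ``loading_quantile`` quantile over all species.  Lowering either
    threshold can only grow the subsets.
    """
    for name, v in (("corr_threshold", corr_threshold),
                    ("loading_quantile", loading_quantile)):
        if not (0.0 < v <= 1.0):
            raise OplsError(f"{name} {v} outside (0, 1]")
    wl = weighted_loadings(model)
    cut = wl.abs().quantile(loading_quantile)
    big = wl.abs() >= cut
    corr = model.corr
    pos = [sp for sp in model.species
           if big[sp] and corr[sp] >= corr_threshold]
    neg = [sp for sp in model.species
           if big[sp] and corr[sp] <= -corr_threshold]
    return SPlotSelection(positive=pos, negative=neg,
                          corr_threshold=corr_threshold,
                          loading_quantile=loading_quantile)


def evaluate_subsets(selection: SPlotSelection, table: AbundanceTable,
                     groups: tuple[str, str]) -> pd.DataFrame:
    """Compare candidate subsets by PCA separation of the two groups.

    For each non-empty subset (positive / negative / union) a PCA is
    refitted on the subset species and the two groups' centroid distance
    along PC1 is reported, together with PC1's share of the total
    between-centroid separation.
    """
    sub_table = table.restrict_groups(groups)
    rows = {}
    for name, species in (("positive", selection.positive),
                          ("negative", selection.negative),
                          ("union", selection.union)):
        if not species:
            continue
        t = sub_table.subset_species(species)
        k = min(len(t.samples) - 1, len(species))
        model = fit_pca(t, components=k)
        cents = {}
        for g in groups:
            rows_g = [s for s in model.scores.index
                      if model.design.get(s) == g]
            cents[g] = model.scores.loc[rows_g].mean(axis=0)
        diff = cents[groups[0]] - cents[groups[1]]
        pc1 = abs(float(diff.iloc[0]))
        total_sq = float((diff ** 2).sum())
        rows[name] = {
            "n_species": len(species),
            "pc1_centroid_distance": pc1,
            "pc1_separation_share": (pc1 ** 2 / total_sq
                                     if total_sq > 0 else np.nan),
        }
    if not rows:
        raise OplsError("all subsets empty")
    return pd.DataFrame.from_dict(rows, orient="index")
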