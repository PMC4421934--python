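"""PCA-based phenotyping: factor scores, per-species discrimination
contributions, contribution tables, projection of independent datasets and
nearest-centroid classification.

The model is ordinary PCA on the samples x species matrix: column
mean-centering, no variance scaling by default (matching the default of the
standard R routine), via singular-value decomposition.  A sample's *factor
score* on component x is the centered abundance-weighted sum of loadings

    PC_x = sum_i (m_i - center_i) * l_{x,i}

and the per-species discrimination contribution between two groups is

    dPC_x(i) = (mean_high(i) - mean_low(i)) * l_{x,i}

where "high" is the group with the higher mean factor score on x.  Because
centering cancels in the difference of means, raw group means can be used;
summed over species the contributions reconstruct the oriented difference
of the group-mean factor scores exactly (linearity).  Positive values
support the separation, negative values argue against it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable

__all__ = [
    "PCAModel",
    "ContributionTable",
    "PCAError",
    "fit_pca",
    "factor_scores",
    "delta_pc_contributions",
    "delta_contribution",
    "contribution_report",
    "project",
    "classify_nearest_centroid",
]

log = logging.getLogger(__name__)


class PCAError(ValueError):
    pass


@dataclass
class PCAModel:
    """A fitted PCA: center, loadings, variances and training scores.

    ``loadings`` is species x components with orthonormal columns;
    ``scores`` is samples x components, equal to ``(X - center) @ loadings``.
    The deterministic sign convention makes the largest-|loading| element
    of each component positive.
    """

    species: list[str]
    center: np.ndarray
    loadings: np.ndarray              # species x components
    explained_variance: np.ndarray    # per component, descending
    scores: pd.DataFrame              # samples x PC1..PCk
    design: dict[str, str] = field(default_factory=dict)
    scaled: bool = False
    scale: np.ndarray | None = None
    sign_convention: str = "max-abs-loading-positive"

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> Path:
        payload = {
            "species": self.species,
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "scores": {s: row.tolist()
                       for s, row in self.scores.iterrows()},
            "design": self.design,
            "scaled": self.scaled,
            "scale": None if self.scale is None else self.scale.tolist(),
            "sign_convention": self.sign_convention,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        loadings = np.asarray(d["loadings"], dtype=float)
        scores = pd.DataFrame.from_dict(d["scores"], orient="index")
        scores.columns = [f"PC{i + 1}" for i in range(loadings.shape[1])]
        return cls(
            species=list(d["species"]),
            center=np.asarray(d["center"], dtype=float),
            loadings=loadings,
            explained_variance=np.asarray(d["explained_variance"],
                                          dtype=float),
            scores=scores,
            design=dict(d.get("design", {})),
            scaled=bool(d.get("scaled", False)),
            scale=(None if d.get("scale") is None
                   else np.asarray(d["scale"], dtype=float)),
            sign_convention=d.get("sign_convention",
                                  "max-abs-loading-positive"),
        )


def _matrix(table: AbundanceTable) -> tuple[np.ndarray, list[str], list[str]]:
    """samples x species float matrix; missing imputed as 0 (no signal)."""
    X = table.data.T.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        log.info("imputing %d not-detected cells as 0 before PCA", n_missing)
        X = np.nan_to_num(X, nan=0.0)
    return X, list(table.data.columns), list(table.data.index)


def fit_pca(table: AbundanceTable, components: int | None = None,
            scale: bool = False) -> PCAModel:
    """Fit PCA by SVD of the column-centered samples x species matrix.

    ``components`` defaults to ``min(samples - 1, species)``.  With
    ``scale=True`` columns are additionally divided by their sample s.d.
    (unit-variance scaling); the default is centering only.
    """
    X, samples, species = _matrix(table)
    n, m = X.shape
    if n < 2:
        raise PCAError("PCA needs at least 2 samples")
    max_k = min(n - 1, m)
    k = max_k if components is None else int(components)
    if not (1 <= k <= max_k):
        raise PCAError(f"components={k} outside [1, {max_k}]")
    center = X.mean(axis=0)
    Xc = X - center
    scale_vec = None
    if scale:
        scale_vec = X.std(axis=0, ddof=1)
        if (scale_vec == 0).any():
            raise PCAError("zero-variance species under scaling")
        Xc = Xc / scale_vec
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:k].T                      # species x k
    variances = (s[:k] ** 2) / (n - 1)
    # deterministic sign: largest-|loading| element of each component positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    scores = Xc @ loadings
    scores_df = pd.DataFrame(scores, index=samples,
                             columns=[f"PC{i + 1}" for i in range(k)])
    return PCAModel(species=species, center=center, loadings=loadings,
                    explained_variance=variances, scores=scores_df,
                    design=dict(table.design), scaled=scale, scale=scale_vec)


def _align_profile(model: PCAModel, profile: pd.Series) -> np.ndarray:
    missing = [sp for sp in model.species if sp not in profile.index]
    if missing:
        raise PCAError(f"profile lacks model species: {missing[:5]}"
                       f"{'...' if len(missing) > 5 else ''}")
    extra = [sp for sp in profile.index if sp not in set(model.species)]
    if extra:
        warnings.warn(f"ignoring {len(extra)} species absent from the model",
                      stacklevel=3)
    v = profile.reindex(model.species).to_numpy(dtype=float)
    return np.nan_to_num(v, nan=0.0)


def factor_scores(model: PCAModel, profile: pd.Series) -> pd.Series:
    """Factor scores of one abundance profile under a fitted model.

    Scores are centered with the training center for consistency with the
    fit; a profile equal to the center lands at the origin.
    """
    v = _align_profile(model, profile) - model.center
    if model.scale is not None:
        v = v / model.scale
    return pd.Series(v @ model.loadings, index=model.component_names())


def project(model: PCAModel, table: AbundanceTable) -> pd.DataFrame:
    """Score every sample of ``table`` against the training center/loadings.

    No refitting happens; extra species in the table are ignored with a
    warning, absent model species are an error.
    """
    rows = {s: factor_scores(model, table.data[s]) for s in table.samples}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ContributionTable:
    """Per-species discrimination contributions on one component.

    ``delta`` is indexed by species; positive entries *support* the
    separation of ``high_group`` from ``low_group`` on the component.
    """

    component: int                 # 1-based
    high_group: str
    low_group: str
    delta: pd.Series

    def ordered(self) -> pd.Series:
        """Supporting species first (descending signed contribution)."""
        return self.delta.sort_values(ascending=False, kind="stable")

    def top(self, k: int) -> list[str]:
        return list(self.ordered().index[:k])

    @property
    def total(self) -> float:
        """Equals the oriented difference of group-mean factor scores."""
        return float(self.delta.sum())


def delta_pc_contributions(mean_a: pd.Series, mean_b: pd.Series,
                           loading: pd.Series,
                           label_a: str = "A",
                           label_b: str = "B") -> ContributionTable:
    """Oriented per-species contributions from two group-mean profiles.

    The group with the higher mean factor score on the component (the
    loading-weighted sum of its means) is the "high" group; each species
    contributes ``(mean_high - mean_low) * loading``.  Centering cancels in
    the mean difference, so raw means are used directly.
    """
    idx = loading.index
    a = mean_a.reindex(idx).fillna(0.0)
    b = mean_b.reindex(idx).fillna(0.0)
    score_a = float(a @ loading)
    score_b = float(b @ loading)
    if score_a == score_b:
        raise PCAError("orientation undefined: equal group-mean scores")
    if score_a > score_b:
        high, low, mh, ml = label_a, label_b, a, b
    else:
        high, low, mh, ml = label_b, label_a, b, a
    delta = (mh - ml) * loading
    delta.name = "delta_pc"
    return ContributionTable(component=0, high_group=high, low_group=low,
                             delta=delta)


def delta_contribution(model: PCAModel, mean_a: pd.Series, mean_b: pd.Series,
                       component: int = 1, label_a: str = "A",
                       label_b: str = "B") -> ContributionTable:
    """Contribution table for component ``component`` (1-based) of a model."""
    if not (1 <= component <= model.n_components):
        raise PCAError(f"component {component} not in model")
    loading = pd.Series(model.loadings[:, component - 1], index=model.species)
    a = pd.Series(_align_profile(model, mean_a), index=model.species)
    b = pd.Series(_align_profile(model, mean_b), index=model.species)
    if model.scale is not None:
        # under unit-variance scaling the mean difference is scaled too
        a = a / model.scale
        b = b / model.scale
    table = delta_pc_contributions(a, b, loading, label_a, label_b)
    table.component = component
    return table


def contribution_report(tables: list[ContributionTable]) -> pd.DataFrame:
    """Stack ordered contribution tables into one long report.

    Within each component species are sorted supporting-first; ties keep
    input order (stable sort).
    """
    if not tables:
        raise PCAError("no contribution tables")
    frames = []
    for t in tables:
        ordered = t.ordered()
        frames.append(pd.DataFrame({
            "component": t.component,
            "pair": f"{t.high_group}-{t.low_group}",
            "species": ordered.index,
            "delta_pc": ordered.to_numpy(),
            "supporting": ordered.to_numpy() > 0,
        }))
    return pd.concat(frames, ignore_index=True)


def classify_nearest_centroid(model: PCAModel, scores: pd.DataFrame,
                              design: dict[str, str] | None = None
                              ) -> pd.DataFrame:
    """Assign each projected sample to the nearest training-group centroid.

    Distances are Euclidean over the retained components.  Ties are broken
    by group-name order with a warning.  Returns a frame with the predicted
    group, its distance, and the distance to every group centroid.
    """
    design = design or model.design
    if not design:
        raise PCAError("no training design for centroids")
    groups = sorted(set(design.values()))
    if len(groups) < 2:
        raise PCAError("need >= 2 training groups")
    centroids = {}
    for g in groups:
        rows = [s for s in model.scores.index if design.get(s) == g]
        if not rows:
            raise PCAError(f"empty training group {g}")
        centroids[g] = model.scores.loc[rows].mean(axis=0)
    cent = pd.DataFrame(centroids).T          # groups x components
    out = {}
    for s, row in scores.iterrows():
        d = np.sqrt(((cent - row) ** 2).sum(axis=1))
        best = d.min()
        winners = d.index[d == best].tolist()
        if len(winners) > 1:
            warnings.warn(f"distance tie for sample {s}: {winners}; "
                          "taking first by name", stacklevel=2)
        out[s] = {"predicted": winners[0], "distance": float(best),
                  **{f"d_{g}": float(d[g]) for g in groups}}
    return pd.DataFrame.from_dict(out, orient="index")
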