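"""Habitat-suitability modelling: variable selection, fitting, evaluation.

The suitability stage follows standard presence/pseudo-absence SDM
practice. Candidate covariates are reduced by a backward collinearity
filter: while any pair of remaining covariates has |Pearson r| above the
correlation threshold (0.8), the member of the most-correlated pair with
the higher variance inflation factor (VIF) is dropped; afterwards the
highest-VIF covariate is dropped repeatedly until every VIF is below the
threshold (4). The suitability learner is a random-forest classifier (a
supplied component with a fixed contract: per-point occurrence probability
and node-impurity importances). Evaluation uses the continuous Boyce index
(the presence-only measure), AUC, Cohen's kappa and the true skill
statistic TSS = sensitivity + specificity - 1; the probability threshold
for kappa/TSS defaults to the one maximizing TSS on the data it is
computed from, recorded in the report.

Covariate tables are plain pandas DataFrames with one row per occurrence
point, covariate columns, and a 0/1 ``label`` column (1 = presence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .errors import DegenerateInputError, SpreadcaError
from .raster import RasterLayer, require_aligned

__all__ = [
    "SelectionConfig", "SelectionResult", "select_variables", "vif",
    "split_train_test", "SuitabilityModel", "fit_suitability",
    "boyce_index", "confusion_metrics", "max_tss_threshold",
    "EvalReport", "evaluate_model",
    "partial_dependence", "variable_importance",
    "project_suitability", "extract_covariates",
]

LABEL_COLUMN = "label"


# -- variable selection -----------------------------------------------------


@dataclass
class SelectionConfig:
    corr_threshold: float = 0.8
    vif_threshold: float = 4.0

    def __post_init__(self):
        if self.corr_threshold <= 0 or self.vif_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class SelectionResult:
    kept: list[str]
    log: list[dict] = field(default_factory=list)


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factors via the R-squared of each column on the rest.

    ``VIF_j = 1 / (1 - R2_j)``; rank-deficient (perfectly predictable)
    columns get ``inf``.
    """
    X = table.to_numpy(dtype=float)
    n, k = X.shape
    out = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(table.columns):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def select_variables(table: pd.DataFrame, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Backward collinearity selection (pairwise correlation, then VIF).

    Phase 1: while the most-correlated remaining pair exceeds
    ``corr_threshold`` in |Pearson r|, drop its higher-VIF member.
    Phase 2: drop the highest-VIF covariate until all VIF are below
    ``vif_threshold``. Ties in VIF (including multiple infinities) break
    deterministically toward the lexicographically later column name.
    Survivors are returned in input-column order, with an audit log of
    every drop.
    """
    cfg = cfg or SelectionConfig()
    covs = [c for c in table.columns if c != LABEL_COLUMN]
    if len(covs) < 2:
        raise ValueError("need at least 2 covariates")
    if len(table) < len(covs) + 2:
        raise ValueError("need at least covariates+2 rows")
    data = table[covs].astype(float)
    remaining = list(covs)
    log: list[dict] = []

    def _drop_choice(candidates: list[str], vifs: pd.Series) -> str:
        vmax = vifs[candidates].max()
        tied = [c for c in candidates if vifs[c] == vmax or
                (np.isinf(vifs[c]) and np.isinf(vmax))]
        return sorted(tied)[-1]

    while len(remaining) >= 2:
        corr = data[remaining].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        idx = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        r = corr.values[idx]
        if r <= cfg.corr_threshold:
            break
        a, b = corr.index[idx[0]], corr.columns[idx[1]]
        vifs = vif(data[remaining])
        drop = _drop_choice([a, b], vifs)
        remaining.remove(drop)
        log.append({"dropped": drop, "rule": "correlation-pair",
                    "pair": (a, b), "abs_r": float(r), "vif": float(vifs[drop])})

    while len(remaining) >= 2:
        vifs = vif(data[remaining])
        if (vifs < cfg.vif_threshold).all():
            break
        drop = _drop_choice(list(remaining), vifs)
        remaining.remove(drop)
        log.append({"dropped": drop, "rule": "vif", "vif": float(vifs[drop])})

    kept = [c for c in covs if c in remaining]
    return SelectionResult(kept=kept, log=log)


# -- split and fit ----------------------------------------------------------


def split_train_test(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0):
    """Label-stratified random split into (train, test), default 7:3."""
    if len(table) < 10:
        raise ValueError("need at least 10 rows to split")
    train, test = train_test_split(
        table, train_size=ratio, stratify=table[LABEL_COLUMN], random_state=seed)
    return train.copy(), test.copy()


@dataclass
class SuitabilityModel:
    """A fitted tree-ensemble suitability model plus its training context."""

    estimator: RandomForestClassifier
    variables: list[str]
    seed: int
    train_features: pd.DataFrame

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Per-row probability of presence."""
        probs = self.estimator.predict_proba(table[self.variables])
        presence_col = list(self.estimator.classes_).index(1)
        return probs[:, presence_col]

    def save(self, path: str | Path) -> None:
        joblib.dump({"estimator": self.estimator, "variables": self.variables,
                     "seed": self.seed, "train_features": self.train_features}, path)

    @classmethod
    def load(cls, path: str | Path) -> "SuitabilityModel":
        blob = joblib.load(path)
        return cls(**blob)


def fit_suitability(train: pd.DataFrame, n_trees: int = 500, seed: int = 0,
                    variables: list[str] | None = None) -> SuitabilityModel:
    """Fit the random-forest suitability classifier on a labelled table."""
    if variables is None:
        variables = [c for c in train.columns if c != LABEL_COLUMN]
    y = train[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training data contains a single class")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(train[variables], y)
    return SuitabilityModel(estimator=rf, variables=list(variables), seed=seed,
                            train_features=train[variables].copy())


# -- evaluation -------------------------------------------------------------


def boyce_index(suit_presence, suit_background, n_windows: int = 101,
                window_width: float = 0.1) -> float:
    """Continuous Boyce index from presence and background suitabilities.

    Moving windows of width ``window_width`` times the suitability range
    slide across the range at ``n_windows`` evenly spaced midpoints; each
    window's predicted-to-expected ratio is the fraction of presences
    falling in the window divided by the fraction of background points
    (windows with zero background are skipped). The index is the Spearman
    rank correlation between window midpoint and P/E — a monotone-
    rescaling-invariant calibration measure in [-1, 1].
    """
    pres = np.asarray(suit_presence, dtype=float)
    bg = np.asarray(suit_background, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background vectors must be nonempty")
    lo = min(pres.min(), bg.min())
    hi = max(pres.max(), bg.max())
    if hi <= lo:
        raise DegenerateInputError("suitability scores are constant")
    width = window_width * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    pe, used_mids = [], []
    for m in mids:
        lo_w, hi_w = m - width / 2, m + width / 2
        p = np.mean((pres >= lo_w) & (pres <= hi_w))
        e = np.mean((bg >= lo_w) & (bg <= hi_w))
        if e == 0:
            continue
        pe.append(p / e)
        used_mids.append(m)
    if len(pe) < 3:
        raise DegenerateInputError(f"only {len(pe)} usable windows (< 3)")
    rho, _ = stats.spearmanr(used_mids, pe)
    return float(rho)


def confusion_metrics(labels, probs, threshold: float) -> dict[str, float]:
    """AUC (rank statistic, ties averaged), kappa, TSS, sensitivity, specificity.

    AUC is threshold-free; kappa/TSS/sens/spec come from the 2x2 table at
    ``probs >= threshold``.
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("both classes must be present")
    pred = (probs >= threshold).astype(int)
    tp = int(((labels == 1) & (pred == 1)).sum())
    fn = int(((labels == 1) & (pred == 0)).sum())
    tn = int(((labels == 0) & (pred == 0)).sum())
    fp = int(((labels == 0) & (pred == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "auc": float(roc_auc_score(labels, probs)),
        "kappa": float(cohen_kappa_score(labels, pred)),
        "tss": sens + spec - 1.0,
        "sens": sens,
        "spec": spec,
    }


def max_tss_threshold(labels, probs) -> float:
    """The probability cut maximizing TSS (lowest such cut on ties)."""
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    cuts = np.unique(probs)
    best_cut, best_tss = cuts[0], -np.inf
    for c in cuts:
        pred = probs >= c
        sens = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
        spec = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_cut = tss, c
    return float(best_cut)


@dataclass
class EvalReport:
    cbi: float
    auc: float
    kappa: float
    tss: float
    threshold: float
    split_ratio: float = 0.7
    seed: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"cbi": self.cbi, "auc": self.auc, "kappa": self.kappa,
                "tss": self.tss, "threshold": self.threshold}


def evaluate_model(labels, probs, threshold: float | None = None,
                   split_ratio: float = 0.7, seed: int = 0) -> EvalReport:
    """All four evaluation statistics for one labelled probability vector.

    CBI uses presences against all points as background; the kappa/TSS
    threshold defaults to the max-TSS cut on these data (recorded).
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    if threshold is None:
        threshold = max_tss_threshold(labels, probs)
    cm = confusion_metrics(labels, probs, threshold)
    cbi = boyce_index(probs[labels == 1], probs)
    return EvalReport(cbi=cbi, auc=cm["auc"], kappa=cm["kappa"], tss=cm["tss"],
                      threshold=threshold, split_ratio=split_ratio, seed=seed)


# -- response diagnostics ---------------------------------------------------


def partial_dependence(model: SuitabilityModel, variable: str, grid) -> np.ndarray:
    """Mean predicted probability with ``variable`` clamped to each grid value."""
    if variable not in model.variables:
        raise KeyError(f"variable {variable!r} not in model {model.variables}")
    grid = np.asarray(grid, dtype=float)
    base = model.train_features.copy()
    curve = np.empty(grid.size)
    for i, v in enumerate(grid):
        base[variable] = v
        curve[i] = model.predict(base).mean()
    return curve


def variable_importance(model: SuitabilityModel) -> list[tuple[str, float]]:
    """Node-impurity-reduction importances, descending."""
    scores = model.estimator.feature_importances_
    order = np.argsort(scores)[::-1]
    return [(model.variables[i], float(scores[i])) for i in order]


# -- spatial projection -----------------------------------------------------


def extract_covariates(points, covariate_rasters: dict[str, RasterLayer],
                       labels=None) -> pd.DataFrame:
    """Sample covariate rasters at point locations into a labelled table.

    ``points`` is an OccurrenceSet (labels inferred from it unless given
    explicitly). Points outside the rasters or on nodata cells are dropped.
    """
    require_aligned(*covariate_rasters.values())
    first = next(iter(covariate_rasters.values()))
    row, col = first.index_of(points.x, points.y)
    inside = (row >= 0) & (row < first.nrows) & (col >= 0) & (col < first.ncols)
    row, col = row[inside], col[inside]
    data = {}
    valid = np.ones(row.shape, dtype=bool)
    for name, layer in covariate_rasters.items():
        vals = layer.values[row, col].astype(float)
        valid &= layer.valid_mask[row, col]
        data[name] = vals
    frame = pd.DataFrame(data)
    if labels is None:
        from .occurrences import LABEL_PRESENCE
        labels = (points.label[inside] == LABEL_PRESENCE).astype(int)
    else:
        labels = np.asarray(labels)[inside]
    frame[LABEL_COLUMN] = labels
    return frame[valid].reset_index(drop=True)


def project_suitability(model: SuitabilityModel,
                        covariate_rasters: dict[str, RasterLayer]) -> RasterLayer:
    """Predict per-cell occurrence probability over aligned covariate rasters.

    Nodata in any covariate propagates to the output (sentinel -1).
    """
    missing = [v for v in model.variables if v not in covariate_rasters]
    if missing:
        raise SpreadcaError(f"missing covariate rasters: {missing}")
    layers = {v: covariate_rasters[v] for v in model.variables}
    require_aligned(*layers.values())
    first = next(iter(layers.values()))
    valid = np.ones(first.shape, dtype=bool)
    for layer in layers.values():
        valid &= layer.valid_mask
    table = pd.DataFrame({v: layers[v].values[valid].astype(float)
                          for v in model.variables})
    out = np.full(first.shape, -1.0)
    if len(table):
        out[valid] = model.predict(table)
    return RasterLayer(values=out, origin_x=first.origin_x, origin_y=first.origin_y,
                       cell_size=first.cell_size, nodata=-1.0, crs_tag=first.crs_tag)
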