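"""Desk-scale ensemble species distribution modelling.

Occurrence cleaning and grid rarefaction, pairwise collinearity filtering of
environmental layers, pseudo-absence generation, multi-learner fitting under
repeated stratified holdout, AUC-thresholded AUC-weighted consensus, and
TSS/Kappa/AUC evaluation with permutation variable importance.

The nine classical SDM algorithm names are represented here by five learner
families built from standard numerical routines: regularized linear
logistic, polynomial logistic, bagged decision trees, boosted stumps, and
k-nearest-neighbour probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import Raster, Stack

__all__ = [
    "BinaryMetrics",
    "EnsembleModel",
    "default_learners",
    "clean_occurrences",
    "rarefy",
    "collinearity_filter",
    "pseudo_absences",
    "fit_ensemble",
    "evaluate_binary",
    "variable_importance",
]


def default_learners(seed: int = 0) -> dict[str, object]:
    """Five learner families mapping env covariates to probabilities."""
    return {
        "logistic": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        ),
        "poly_logistic": make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(max_iter=2000),
        ),
        "bagged_trees": BaggingClassifier(
            DecisionTreeClassifier(random_state=seed),
            n_estimators=25,
            random_state=seed,
        ),
        "boosted_stumps": GradientBoostingClassifier(
            max_depth=1, n_estimators=80, random_state=seed
        ),
        "knn": make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=15)
        ),
    }


# ---------------------------------------------------------------------------
# Occurrence handling
# ---------------------------------------------------------------------------


def clean_occurrences(
    raw: pd.DataFrame, extent: tuple[float, float, float, float] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop common coordinate errors; report counts per rule.

    Rules, applied in order: non-finite coordinates, lon/lat out of valid
    range, exact (0, 0) points, points outside the study extent, exact
    duplicates.
    """
    df = raw[["lon", "lat"]].astype(float).copy()
    report: dict[str, int] = {}

    finite = np.isfinite(df["lon"]) & np.isfinite(df["lat"])
    report["non_finite"] = int((~finite).sum())
    df = df[finite]

    in_range = df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    report["out_of_range"] = int((~in_range).sum())
    df = df[in_range]

    zero_zero = (df["lon"] == 0) & (df["lat"] == 0)
    report["zero_zero"] = int(zero_zero.sum())
    df = df[~zero_zero]

    if extent is not None:
        xmin, xmax, ymin, ymax = extent
        inside = df["lon"].between(xmin, xmax) & df["lat"].between(ymin, ymax)
        report["out_of_extent"] = int((~inside).sum())
        df = df[inside]
    else:
        report["out_of_extent"] = 0

    before = len(df)
    df = df.drop_duplicates()
    report["duplicates"] = before - len(df)

    if df.empty:
        raise ValueError("no occurrence points survive cleaning")
    return df.reset_index(drop=True), report


def rarefy(points: pd.DataFrame, resolution: float, seed: int = 0) -> pd.DataFrame:
    """Spatial thinning: keep at most one point per grid cell.

    The retained point in each occupied cell is chosen uniformly at random
    (seeded).  The thinning grid is anchored at the points' lower-left
    corner.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    if points.empty:
        return points.copy()
    x0 = points["lon"].min()
    y0 = points["lat"].min()
    cx = np.floor((points["lon"].to_numpy() - x0) / resolution).astype(int)
    cy = np.floor((points["lat"].to_numpy() - y0) / resolution).astype(int)
    rng = np.random.default_rng(seed)
    keep_rows = []
    cells = pd.DataFrame({"cx": cx, "cy": cy})
    for _, idx in cells.groupby(["cx", "cy"], sort=True).indices.items():
        keep_rows.append(int(rng.choice(idx)))
    return points.iloc[sorted(keep_rows)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Environmental layers
# ---------------------------------------------------------------------------


def collinearity_filter(
    stack: Stack, threshold: float = 0.80
) -> tuple[Stack, list[str]]:
    """Iteratively drop layers until all pairwise |Pearson r| < threshold.

    At each step the worst pair is found and the member with the larger mean
    absolute correlation to the remaining layers is removed.
    """
    if len(stack) < 2:
        return stack, []
    names = stack.names
    M = stack.matrix()
    corr = pd.DataFrame(np.corrcoef(M, rowvar=False), index=names, columns=names)
    retained = list(names)
    dropped: list[str] = []
    while len(retained) > 1:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.stack().idxmax()
        if sub.loc[worst] < threshold:
            break
        a, b = worst
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        victim = a if mean_a >= mean_b else b
        retained.remove(victim)
        dropped.append(victim)
    return stack.subset(retained), dropped


def pseudo_absences(
    stack: Stack, presences: pd.DataFrame, n: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Uniform random background cells excluding presence cells and nodata.

    Default n equals the presence count (balanced design).
    """
    n = len(presences) if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = stack.grid
    valid = stack.valid_mask()
    prow, pcol = grid.index_of(presences["lon"].to_numpy(), presences["lat"].to_numpy())
    inb = grid.in_bounds(presences["lon"].to_numpy(), presences["lat"].to_numpy())
    occupied = np.zeros_like(valid)
    occupied[prow[inb], pcol[inb]] = True
    eligible = valid & ~occupied
    flat_idx = np.flatnonzero(eligible.ravel())
    if len(flat_idx) < n:
        raise ValueError(
            f"only {len(flat_idx)} eligible background cells for n={n}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(flat_idx, size=n, replace=False)
    rows, cols = np.unravel_index(pick, valid.shape)
    return pd.DataFrame(
        {"lon": grid.lon_centers()[cols], "lat": grid.lat_centers()[rows]}
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryMetrics:
    auc: float
    kappa: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "kappa": self.kappa,
            "tss": self.tss,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
        }


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formula, ties by midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_binary(scores, labels) -> BinaryMetrics:
    """AUC plus TSS/Kappa/sensitivity/specificity at the max-TSS threshold.

    Thresholds sweep the unique score values; predictions are positive at
    score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc = rank_auc(scores, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1

    best = None
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        sens = tp / n1
        spec = (n0 - fp) / n0
        tss = sens + spec - 1.0
        if best is None or tss > best[0] + 1e-15:
            best = (tss, t, sens, spec, tp, fp)
    tss, thr, sens, spec, tp, fp = best
    fn, tn = n1 - tp, n0 - fp
    n = n1 + n0
    po = (tp + tn) / n
    pe = ((tp + fp) * n1 + (fn + tn) * n0) / n**2
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return BinaryMetrics(auc=auc, kappa=float(kappa), tss=float(tss),
                         sensitivity=float(sens), specificity=float(spec),
                         threshold=float(thr))


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    learner_auc: dict[str, float]
    included: dict[str, bool]
    weights: dict[str, float]          # included learners, sum to 1
    consensus: Raster
    metrics: BinaryMetrics             # pooled-holdout ensemble metrics
    learner_correlations: pd.DataFrame
    variables: list[str]
    fitted: dict[str, object] = field(repr=False, default_factory=dict)
    train_X: np.ndarray | None = field(repr=False, default=None)
    train_y: np.ndarray | None = field(repr=False, default=None)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Weighted-consensus probability for an (n, p) covariate matrix."""
        out = np.zeros(X.shape[0])
        for name, w in self.weights.items():
            out += w * self.fitted[name].predict_proba(X)[:, 1]
        return out

    def predict(self, stack: Stack) -> Raster:
        """Consensus suitability raster on a (possibly different) stack."""
        if stack.names != self.variables:
            stack = stack.subset(self.variables)
        mask = stack.valid_mask()
        X = stack.matrix(mask)
        vals = np.full(mask.shape, np.nan)
        vals[mask] = np.clip(self.predict_matrix(X), 0.0, 1.0)
        return Raster(vals, stack.grid)


def _point_matrix(stack: Stack, points: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = stack.sample(points["lon"].to_numpy(), points["lat"].to_numpy())
    ok = np.isfinite(X).all(axis=1)
    return X, ok


def fit_ensemble(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: Stack,
    learners: dict[str, object] | None = None,
    repeats: int = 10,
    train_fraction: float = 0.75,
    auc_threshold: float = 0.75,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the AUC-weighted consensus model.

    Per repeat, a stratified train/holdout split; per learner, the mean
    holdout AUC over repeats.  Learners at or above `auc_threshold` enter
    the consensus with weights proportional to their AUC; the consensus is
    the weighted mean probability.  Ensemble AUC/Kappa/TSS are computed on
    pooled holdout consensus predictions at the TSS-maximizing threshold.
    """
    if learners is None:
        learners = default_learners(seed)
    if len(learners) < 3:
        raise ValueError("need at least 3 learner families")
    Xp, okp = _point_matrix(stack, presences)
    Xb, okb = _point_matrix(stack, background)
    if (~okp).any():
        warnings.warn(f"{int((~okp).sum())} presence points on nodata cells dropped")
    X = np.vstack([Xp[okp], Xb[okb]])
    y = np.concatenate([np.ones(int(okp.sum())), np.zeros(int(okb.sum()))])

    names = list(learners)
    holdout_preds: dict[str, list[np.ndarray]] = {n: [] for n in names}
    holdout_labels: list[np.ndarray] = []
    aucs: dict[str, list[float]] = {n: [] for n in names}

    for rep in range(repeats):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=train_fraction, stratify=y, random_state=seed + rep
        )
        holdout_labels.append(yte)
        for name in names:
            model = clone(learners[name])
            model.fit(Xtr, ytr)
            p = model.predict_proba(Xte)[:, 1]
            holdout_preds[name].append(p)
            aucs[name].append(rank_auc(p, yte))

    learner_auc = {n: float(np.mean(aucs[n])) for n in names}
    included = {n: learner_auc[n] >= auc_threshold for n in names}
    if not any(included.values()):
        raise ValueError(
            "no learner reached the inclusion AUC threshold "
            f"{auc_threshold}; inspect the data or lower the threshold"
        )
    wsum = sum(learner_auc[n] for n in names if included[n])
    weights = {n: learner_auc[n] / wsum for n in names if included[n]}

    # pooled holdout consensus metrics
    pooled_labels = np.concatenate(holdout_labels)
    pooled_pred = np.zeros_like(pooled_labels, dtype=float)
    for n, w in weights.items():
        pooled_pred += w * np.concatenate(holdout_preds[n])
    metrics = evaluate_binary(pooled_pred, pooled_labels)

    # final refit on all data; consensus raster and learner correlations
    mask = stack.valid_mask()
    Xgrid = stack.matrix(mask)
    fitted: dict[str, object] = {}
    grid_preds: dict[str, np.ndarray] = {}
    for name in names:
        model = clone(learners[name])
        model.fit(X, y)
        fitted[name] = model
        grid_preds[name] = model.predict_proba(Xgrid)[:, 1]
    corr = pd.DataFrame(
        np.corrcoef(np.column_stack([grid_preds[n] for n in names]), rowvar=False),
        index=names, columns=names,
    )
    consensus_vals = np.full(mask.shape, np.nan)
    consensus_vals[mask] = np.clip(
        sum(w * grid_preds[n] for n, w in weights.items()), 0.0, 1.0
    )

    return EnsembleModel(
        learner_auc=learner_auc,
        included=included,
        weights=weights,
        consensus=Raster(consensus_vals, stack.grid),
        metrics=metrics,
        learner_correlations=corr,
        variables=stack.names,
        fitted=fitted,
        train_X=X,
        train_y=y,
    )


def variable_importance(model: EnsembleModel, stack: Stack, seed: int = 0) -> pd.Series:
    """Permutation importance of each layer, normalized to sum to 100.

    Importance of a variable is 1 minus the Pearson correlation between
    consensus predictions on intact covariates and on covariates with that
    variable's cell values permuted (seeded); negatives clip to 0.
    """
    if stack.names != model.variables:
        stack = stack.subset(model.variables)
    mask = stack.valid_mask()
    X = stack.matrix(mask)
    base = model.predict_matrix(X)
    rng = np.random.default_rng(seed)
    raw = {}
    for j, name in enumerate(model.variables):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        pred = model.predict_matrix(Xp)
        if np.std(pred) == 0 or np.std(base) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(base, pred)[0, 1])
        raw[name] = max(0.0, 1.0 - r)
    total = sum(raw.values())
    if total == 0:
        out = {n: 100.0 / len(raw) for n in raw}
    else:
        out = {n: 100.0 * v / total for n, v in raw.items()}
    return pd.Series(out, name="importance")
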