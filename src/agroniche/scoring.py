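"""Multi-criteria germplasm scoring.

Entropy weighting of normalized trait matrices, Deng-style grey relational
analysis against a yield reference series, PCA-based trait contribution
screening, fuzzy membership-function comprehensive scores, and hierarchical
cluster cuts at fixed Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "WeightVector",
    "GreyConfig",
    "GreyResult",
    "MembershipResult",
    "entropy_weights",
    "grey_relational",
    "pca_contributions",
    "membership_scores",
    "hcluster_cut",
]


@dataclass
class WeightVector:
    """Per-criterion entropy weights with their entropy/divergence terms."""

    weights: pd.Series
    entropy: pd.Series
    divergence: pd.Series

    def __post_init__(self) -> None:
        w = self.weights
        if (w < -1e-12).any():
            raise ValueError("weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class GreyConfig:
    """Grey relational analysis settings."""

    rho: float = 0.5  # resolution coefficient

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("resolution coefficient must lie in (0, 1]")


@dataclass
class GreyResult:
    degrees: pd.Series        # gamma per factor, in (0, 1]
    ranks: pd.Series          # 1 = most related
    coefficients: pd.DataFrame  # xi, observations x factors
    delta_min: float
    delta_max: float


@dataclass
class MembershipResult:
    scores: pd.Series            # per germplasm, in [0, 1]
    selected_traits: list[str]
    dropped_traits: list[str] = field(default_factory=list)


def entropy_weights(normalized: pd.DataFrame) -> WeightVector:
    """Entropy weights of a matrix already normalized to [0, 1].

    p_ij = x_ij / sum_i x_ij; e_j = -(1/ln n) sum_i p_ij ln p_ij with
    0 ln 0 := 0; divergence d_j = 1 - e_j; w_j = d_j / sum d_j.  An all-zero
    or constant column gets weight 0; if every column is constant the
    weights fall back to uniform with a warning.
    """
    X = normalized.to_numpy(dtype=float)
    if np.nanmin(X) < -1e-12 or np.nanmax(X) > 1 + 1e-12:
        raise ValueError("entries must lie in [0, 1]; normalize first")
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    cols = list(normalized.columns)
    colsum = X.sum(axis=0)
    e = np.ones(m)
    for j in range(m):
        if colsum[j] == 0:
            e[j] = 1.0  # zero divergence -> zero weight
            continue
        p = X[:, j] / colsum[j]
        p = p[p > 0]
        e[j] = float(-(p * np.log(p)).sum() / np.log(n))
    d = 1.0 - e
    d[d < 0] = 0.0  # numerical guard
    total = d.sum()
    if total == 0:
        warnings.warn("all columns carry zero divergence; falling back to uniform weights")
        w = np.full(m, 1.0 / m)
    else:
        w = d / total
    idx = pd.Index(cols, name="trait")
    return WeightVector(
        weights=pd.Series(w, index=idx, name="weight"),
        entropy=pd.Series(e, index=idx, name="entropy"),
        divergence=pd.Series(d, index=idx, name="divergence"),
    )


def grey_relational(
    reference: pd.Series,
    factors: pd.DataFrame,
    cfg: GreyConfig | None = None,
    obs_weights: pd.Series | None = None,
    factor_weights: pd.Series | None = None,
) -> GreyResult:
    """Deng grey relational degrees of factor series against a reference.

    Inputs are expected on a comparable (min-max normalized) scale.
    Delta_i(k) = |ref(k) - factor_i(k)|; per-point coefficient
    xi_i(k) = (Dmin + rho*Dmax) / (Delta_i(k) + rho*Dmax) with Dmin/Dmax
    global over all factors and observations; gamma_i is the obs_weights
    mean of xi_i(k) (uniform by default).

    `factor_weights` optionally rescales factor (and reference) series by
    m * w_j before the deviations are taken — the "weight the criteria,
    then correlate" reading; uniform factor weights reduce to the plain
    analysis.
    """
    cfg = cfg or GreyConfig()
    if not reference.index.equals(factors.index):
        factors = factors.loc[reference.index]
    ref = reference.to_numpy(dtype=float)
    F = factors.to_numpy(dtype=float)
    n, m = F.shape

    if factor_weights is not None:
        fw = factor_weights.reindex(factors.columns).to_numpy(dtype=float)
        if np.any(~np.isfinite(fw)):
            raise ValueError("factor_weights must cover every factor")
        F = F * (m * fw)[None, :]

    if obs_weights is None:
        ow = np.full(n, 1.0 / n)
    else:
        ow = obs_weights.reindex(reference.index).to_numpy(dtype=float)
        ow = ow / ow.sum()

    delta = np.abs(ref[:, None] - F)
    dmin = float(delta.min())
    dmax = float(delta.max())
    if dmax == 0:
        warnings.warn("all series identical to the reference; degrees are all 1")
        xi = np.ones_like(delta)
    else:
        xi = (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)
    gamma = xi.T @ ow
    degrees = pd.Series(gamma, index=factors.columns, name="relational_degree")
    order = degrees.sort_values(ascending=False, kind="stable").index
    ranks = pd.Series(np.arange(1, m + 1), index=order, name="rank").reindex(factors.columns)
    return GreyResult(
        degrees=degrees,
        ranks=ranks,
        coefficients=pd.DataFrame(xi, index=factors.index, columns=factors.columns),
        delta_min=dmin,
        delta_max=dmax,
    )


def pca_contributions(
    matrix: pd.DataFrame,
    variance_target: float = 0.60,
    contribution_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-trait PCA contributions (%) on the correlation scale.

    Axes are retained until the cumulative explained variance reaches
    `variance_target`; each trait's contribution is the eigenvalue-weighted
    mean of its per-axis squared-loading contributions, scaled to sum to
    100.  Traits at or above `contribution_threshold` (default: the uniform
    share 100/m) are flagged selected.

    Returns a DataFrame with columns contribution, selected, plus
    attrs["explained_variance"] and attrs["n_axes"].
    """
    n, m = matrix.shape
    if n < 3 or m < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("constant columns dropped from PCA")
    cols = [c for c, k in zip(matrix.columns, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    total_var = eigval.sum()
    cum = np.cumsum(eigval) / total_var
    n_axes = int(np.searchsorted(cum, variance_target) + 1)
    n_axes = min(n_axes, int((eigval > 1e-12).sum()))
    lam = eigval[:n_axes]
    # per-axis contributions: squared loading entries, each axis sums to 100
    per_axis = 100.0 * eigvec[:, :n_axes] ** 2
    contrib = per_axis @ lam / lam.sum()
    contrib = 100.0 * contrib / contrib.sum()
    mm = len(cols)
    thr = contribution_threshold if contribution_threshold is not None else 100.0 / mm
    out = pd.DataFrame(
        {"contribution": contrib, "selected": contrib >= thr},
        index=pd.Index(cols, name="trait"),
    )
    out.attrs["explained_variance"] = float(cum[n_axes - 1] * 100.0)
    out.attrs["n_axes"] = n_axes
    return out


def membership_scores(
    matrix: pd.DataFrame,
    orientations: dict[str, str] | None = None,
    weights: pd.Series | None = None,
) -> MembershipResult:
    """Fuzzy membership comprehensive scores over the selected traits.

    Each trait maps to [0, 1] by min-max position (reversed for cost
    traits); a germplasm's score is the weighted mean of its memberships
    (equal weights by default).  Constant traits are dropped with a warning.
    """
    if matrix.shape[1] == 0:
        raise ValueError("selected trait set is empty")
    orientations = orientations or {}
    dropped = [c for c in matrix.columns if matrix[c].max() == matrix[c].min()]
    if dropped:
        warnings.warn(f"constant traits dropped from membership scoring: {dropped}")
    kept = [c for c in matrix.columns if c not in dropped]
    if not kept:
        raise ValueError("all selected traits are constant")
    from .traits import min_max_normalize  # local import avoids a cycle

    U = min_max_normalize(matrix[kept], orientations)
    if weights is None:
        w = pd.Series(1.0 / len(kept), index=kept)
    else:
        w = weights.reindex(kept).astype(float)
        w = w / w.sum()
    scores = (U * w).sum(axis=1)
    scores.name = "membership_score"
    return MembershipResult(scores=scores, selected_traits=kept, dropped_traits=dropped)


def hcluster_cut(
    vectors: pd.DataFrame | pd.Series,
    cut_height: float,
    linkage: str = "average",
) -> pd.Series:
    """Agglomerative (Euclidean) clustering cut at a fixed merge height.

    Class labels are integers 1..K ordered by descending class mean of the
    clustered values (row means for multivariate input).  A non-positive
    cut height makes every item its own class.
    """
    if isinstance(vectors, pd.Series):
        frame = vectors.to_frame()
    else:
        frame = vectors
    if len(frame) < 2:
        raise ValueError("need at least 2 items to cluster")
    X = frame.to_numpy(dtype=float)
    if cut_height <= 0:
        labels = np.arange(1, len(frame) + 1)
        order_stat = X.mean(axis=1)
    else:
        method = {"upgma": "average", "ward": "ward"}.get(linkage, linkage)
        Z = hierarchy.linkage(pdist(X), method=method)
        raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        order_stat = X.mean(axis=1)
        labels = raw
    # relabel so that class 1 has the highest mean of the clustered value
    labels = np.asarray(labels)
    class_means = {lab: float(order_stat[labels == lab].mean()) for lab in np.unique(labels)}
    remap = {old: new for new, old in enumerate(
        sorted(class_means, key=class_means.get, reverse=True), start=1)}
    out = pd.Series([remap[lab] for lab in labels], index=frame.index, name="class")
    return out
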