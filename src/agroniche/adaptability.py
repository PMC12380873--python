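"""Introduction-adaptability prediction.

Per-region suitability/environment profiles, optimal-dissimilarity index
screening, Mantel permutation tests on distance matrices, and the
germplasm-by-region adaptability matrix: a similarity-gated product of the
membership comprehensive score, the region's mean suitability, and the
rescaled Spearman similarity between the region's environmental profile and
the trial site's, with permutation significance and Jenks 3-level classing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

from .geo import jenks_breaks
from .grids import Raster, RegionSet, Stack
from . import geo as _geo

__all__ = [
    "MantelResult",
    "AdaptabilityResult",
    "region_profiles",
    "optimal_dissimilarity",
    "mantel",
    "adaptability_matrix",
    "region_similarity_matrix",
]

ADAPT_CLASS_NAMES = {0: "none", 1: "low", 2: "high"}


def region_profiles(
    suitability: Raster,
    stack: Stack,
    regions: RegionSet,
    classmap: Raster | None = None,
) -> pd.DataFrame:
    """Zonal profiles: suitability mean/median, layer means, suitable area.

    Cells are assigned to regions by center containment; regions without
    cells are dropped with a warning.  `classmap` (a classified suitability
    raster where class >= 1 means suitable) feeds suitable_area_km2; without
    it the column is NaN.
    """
    if len(regions) == 0:
        raise ValueError("region set is empty")
    assign = regions.assign_cells(suitability.grid)
    vals = suitability.values
    finite = np.isfinite(vals)
    areas = _geo._area_grid(suitability.grid)
    rows = []
    dropped = []
    for ridx, rid in enumerate(regions.ids):
        sel = (assign == ridx) & finite
        if not sel.any():
            dropped.append(rid)
            continue
        row: dict[str, object] = {
            "region_id": rid,
            "mean_suitability": float(vals[sel].mean()),
            "median_suitability": float(np.median(vals[sel])),
        }
        for name, arr in stack.layers.items():
            row[f"env_{name}"] = float(np.nanmean(arr[sel]))
        if classmap is not None:
            suitable = sel & np.isfinite(classmap.values) & (classmap.values >= 1)
            row["suitable_area_km2"] = float(areas[suitable].sum())
        else:
            row["suitable_area_km2"] = np.nan
        rows.append(row)
    if dropped:
        warnings.warn(f"regions without cells dropped: {dropped}")
    if not rows:
        raise ValueError("no region contains any raster cell")
    return pd.DataFrame(rows).set_index("region_id")


def _gower(F: np.ndarray) -> np.ndarray:
    """Gower dissimilarity for all-numeric features: range-scaled mean |diff|."""
    rng = F.max(axis=0) - F.min(axis=0)
    rng[rng == 0] = 1.0
    return pdist(F / rng, metric="cityblock") / F.shape[1]


_CANDIDATES = {
    "euclidean": lambda F: pdist(F, metric="euclidean"),
    "manhattan": lambda F: pdist(F, metric="cityblock"),
    "bray-curtis": lambda F: pdist(F, metric="braycurtis"),
    "gower": _gower,
}


def optimal_dissimilarity(
    profiles: pd.DataFrame,
    candidates: tuple[str, ...] = ("euclidean", "manhattan", "bray-curtis", "gower"),
) -> tuple[str, pd.Series]:
    """Screen dissimilarity indices against the suitability structure.

    For each candidate, the Spearman rank correlation between the pairwise
    profile dissimilarities (environmental feature columns, env_*) and the
    pairwise absolute differences in mean suitability is computed; the
    candidate maximizing it wins, ties resolved by candidate order.
    """
    if len(profiles) < 4:
        raise ValueError("need at least 4 regions")
    feat_cols = [c for c in profiles.columns if c.startswith("env_")]
    if not feat_cols:
        raise ValueError("profiles carry no environmental feature columns")
    F = profiles[feat_cols].to_numpy(dtype=float)
    if np.all(F.std(axis=0) == 0):
        raise ValueError("constant profiles: dissimilarities undefined")
    target = pdist(profiles[["mean_suitability"]].to_numpy(dtype=float),
                   metric="cityblock")
    scores = {}
    for name in candidates:
        d = _CANDIDATES[name](F)
        if np.std(d) == 0 or np.std(target) == 0:
            scores[name] = 0.0 if np.std(d) == 0 and np.std(target) != 0 else 1.0
        else:
            scores[name] = float(spearmanr(d, target).statistic)
    series = pd.Series(scores, name="rank_correlation")
    best = max(candidates, key=lambda nm: scores[nm])  # ties -> first by order
    return best, series


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    permutations: int
    method: str
    exact: bool
    seed: int | None


def _offdiag(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _mantel_stat(d1: np.ndarray, D2: np.ndarray, perm: np.ndarray, method: str) -> float:
    d2 = _offdiag(D2[np.ix_(perm, perm)])
    if method == "spearman":
        return float(spearmanr(d1, d2).statistic)
    return float(pearsonr(d1, d2).statistic)


def mantel(
    D1,
    D2,
    method: str = "spearman",
    permutations: int = 999,
    seed: int | None = None,
    exact: bool | str = "auto",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the (Spearman or Pearson) correlation of the
    off-diagonal upper triangles; the null permutes rows and columns of D2
    simultaneously.  With exact="auto", n with n! <= 720 gets the exactly
    enumerated permutation distribution (p = proportion of permutations with
    statistic >= observed); otherwise p = (1 + #{perm >= observed}) /
    (permutations + 1).  exact=False forces Monte-Carlo sampling.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    n = D1.shape[0]
    for name, D in (("D1", D1), ("D2", D2)):
        if D.shape != (n, n):
            raise ValueError("matrices must be square and of equal size")
        if not np.allclose(D, D.T):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(D), 0):
            raise ValueError(f"{name} has a non-zero diagonal")
    if n < 4:
        raise ValueError("need at least 4 items")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")

    d1 = _offdiag(D1)
    obs = _mantel_stat(d1, D2, np.arange(n), method)

    if exact is True or (exact == "auto" and math.factorial(n) <= 720):
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if _mantel_stat(d1, D2, np.array(perm), method) >= obs - 1e-12:
                count += 1
        return MantelResult(obs, count / total, total, method, True, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if _mantel_stat(d1, D2, perm, method) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (permutations + 1)
    return MantelResult(obs, p, permutations, method, False, seed)


def region_similarity_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Region x region Spearman correlation of environmental profiles."""
    feat_cols = [c for c in profiles.columns if c.startswith("env_")]
    F = profiles[feat_cols].to_numpy(dtype=float)
    rho = spearmanr(F.T).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=profiles.index, columns=profiles.index)


@dataclass
class AdaptabilityResult:
    matrix: pd.DataFrame        # long: germplasm, region, score, p, class
    similarity: pd.Series       # sim(r) per region
    breaks: np.ndarray
    suitable_area: pd.Series    # per germplasm, km^2


def adaptability_matrix(
    membership: pd.Series,
    profiles: pd.DataFrame,
    trial_profile: pd.Series,
    permutations: int = 199,
    seed: int = 0,
) -> AdaptabilityResult:
    """Germplasm x region adaptability scores with permutation significance.

    sim(r) is the Spearman correlation between region r's environmental
    feature vector (env_* columns) and the trial site's; the score is
    A(g, r) = M(g) * S(r) * (1 + max(sim(r), -1)) / 2 with M the membership
    comprehensive score and S the region mean suitability.  Significance per
    region comes from permuting the trial site's feature order (seeded);
    scores are classed {none, low, high} by Jenks k=3 over all pairs.
    Suitable-introduction area per germplasm sums the suitable area of its
    regions classed low or high.
    """
    feat_cols = [c for c in profiles.columns if c.startswith("env_")]
    missing = [c for c in feat_cols if c not in trial_profile.index]
    if missing or not feat_cols:
        raise ValueError(f"trial profile lacks features {missing or feat_cols}")
    if ((membership < -1e-9) | (membership > 1 + 1e-9)).any():
        raise ValueError("membership scores must lie in [0, 1]")
    F = profiles[feat_cols].to_numpy(dtype=float)
    t = trial_profile[feat_cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(t)) for _ in range(permutations)]

    sims, pvals = {}, {}
    for rid, frow in zip(profiles.index, F):
        s = spearmanr(frow, t).statistic
        s = 0.0 if not np.isfinite(s) else float(s)
        sims[rid] = s
        count = 0
        for perm in perms:
            sp = spearmanr(frow, t[perm]).statistic
            sp = 0.0 if not np.isfinite(sp) else float(sp)
            if sp >= s - 1e-12:
                count += 1
        pvals[rid] = (1 + count) / (permutations + 1)
    sim = pd.Series(sims, name="similarity")

    suit = profiles["mean_suitability"]
    rows = []
    for g, m in membership.items():
        for rid in profiles.index:
            gate = (1.0 + max(sim[rid], -1.0)) / 2.0
            rows.append({
                "germplasm_id": g,
                "region_id": rid,
                "score": float(m) * float(suit[rid]) * gate,
                "p": pvals[rid],
            })
    long = pd.DataFrame(rows)

    scores = long["score"].to_numpy()
    if np.unique(scores).size >= 3:
        breaks = jenks_breaks(scores, k=3)
    else:
        breaks = np.array([])
    if breaks.size:
        cls = np.digitize(scores, breaks, right=True)
    else:
        cls = np.zeros(len(scores), dtype=int)
    long["class"] = [ADAPT_CLASS_NAMES.get(int(c), str(c)) for c in cls]

    area = profiles["suitable_area_km2"]
    suitable_area = {}
    for g in membership.index:
        sub = long[(long["germplasm_id"] == g) & (long["class"] != "none")]
        suitable_area[g] = float(area.reindex(sub["region_id"]).fillna(0.0).sum())
    return AdaptabilityResult(
        matrix=long,
        similarity=sim,
        breaks=breaks,
        suitable_area=pd.Series(suitable_area, name="suitable_area_km2"),
    )
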