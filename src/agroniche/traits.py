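"""Descriptive trait statistics: fertility filtering, descriptive/variation
summaries, leaf-area correction, min-max normalization, Shannon trait
diversity and the Pearson correlation matrix of trait means."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptiveStats",
    "TraitConfig",
    "filter_fertility",
    "describe",
    "cv_percent",
    "leaf_area",
    "min_max_normalize",
    "shannon_trait_diversity",
    "pearson_matrix",
    "trait_means",
]


@dataclass(frozen=True)
class DescriptiveStats:
    """min/max/mean, sample (n-1) std and CV in percent."""

    min: float
    max: float
    mean: float
    std: float
    cv: float | None  # percent; None when the mean is zero

    def as_dict(self) -> dict[str, float | None]:
        return {"min": self.min, "max": self.max, "mean": self.mean,
                "std": self.std, "cv": self.cv}


@dataclass(frozen=True)
class TraitConfig:
    """Trait-measurement constants."""

    leaf_area_coefficient: float = 0.8317

    def __post_init__(self) -> None:
        if not self.leaf_area_coefficient > 0:
            raise ValueError("leaf_area_coefficient must be positive")


def filter_fertility(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop germplasms that did not complete the fertility period.

    Returns (filtered table, number of germplasms removed).
    """
    if "fertility_completed" not in table.columns:
        raise ValueError("table lacks a fertility_completed column")
    flag = table.groupby("germplasm_id")["fertility_completed"].first()
    keep = flag[flag].index
    n_removed = int((~flag).sum())
    if len(keep) == 0:
        raise ValueError("all germplasms failed the fertility period; nothing to analyse")
    out = table[table["germplasm_id"].isin(keep)].reset_index(drop=True)
    return out, n_removed


def cv_percent(mean: float, std: float) -> float | None:
    """Coefficient of variation in percent, 100*std/mean; None at mean 0."""
    if mean == 0:
        return None
    return 100.0 * std / mean


def describe(values) -> DescriptiveStats:
    """Descriptive statistics of a replicate vector (sample std, CV%)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(v.mean())
    std = float(v.std(ddof=1))
    cv = cv_percent(mean, std)
    if cv is None:
        warnings.warn("mean is zero: CV undefined, reported as missing")
    return DescriptiveStats(min=float(v.min()), max=float(v.max()),
                            mean=mean, std=std, cv=cv)


def leaf_area(length: float, width: float, cfg: TraitConfig | None = None) -> float:
    """Corrected leaf area = length * width * R (cm^2)."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    cfg = cfg or TraitConfig()
    return length * width * cfg.leaf_area_coefficient


def trait_means(table: pd.DataFrame) -> pd.DataFrame:
    """Germplasm x trait matrix of replicate means (long table in)."""
    return table.pivot_table(index="germplasm_id", columns="trait",
                             values="value", aggfunc="mean")


def min_max_normalize(
    matrix: pd.DataFrame, orientations: dict[str, str] | None = None
) -> pd.DataFrame:
    """Min-max normalize each column into [0, 1].

    Benefit columns map x -> (x-min)/(max-min); cost columns are reversed.
    Constant columns become all zeros with a warning (their entropy weight
    is zero downstream).
    """
    orientations = orientations or {}
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for col in matrix.columns:
        x = matrix[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"column {col!r} is constant; normalized to zeros")
            out[col] = 0.0
            continue
        if orientations.get(col, "benefit") == "cost":
            out[col] = (hi - x) / (hi - lo)
        else:
            out[col] = (x - lo) / (hi - lo)
    return out


def shannon_trait_diversity(block: pd.DataFrame) -> tuple[float, pd.Series]:
    """Trait-diversity index of one germplasm's replicate block.

    For each trait column, H_t = -sum_i p_i ln p_i with p_i the replicate's
    share of the column total; the index is the SUM of H_t over traits
    (per-trait components are returned alongside).  Traits whose replicates
    are all zero contribute 0 with a warning.
    """
    vals = block.astype(float)
    if (vals.values < 0).any():
        raise ValueError("replicate values must be non-negative")
    per_trait = {}
    for col in vals.columns:
        x = vals[col].to_numpy()
        total = x.sum()
        if total == 0:
            warnings.warn(f"trait {col!r} has all-zero replicates; contributes 0")
            per_trait[col] = 0.0
            continue
        p = x / total
        p = p[p > 0]
        per_trait[col] = float(-(p * np.log(p)).sum())
    series = pd.Series(per_trait, name="shannon")
    return float(series.sum()), series


def pearson_matrix(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r matrix with two-tailed p (t transform, n-2 df).

    Zero-variance traits yield NaN rows/columns with a warning.
    """
    n = len(means)
    if n < 3:
        raise ValueError("need at least 3 germplasms")
    cols = list(means.columns)
    X = means.to_numpy(dtype=float)
    sds = X.std(axis=0)
    degenerate = [c for c, s in zip(cols, sds) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance traits {degenerate}: correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    for i, c in enumerate(cols):
        if sds[i] == 0:
            r[i, :] = np.nan
            r[:, i] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    for i, c in enumerate(cols):
        if sds[i] == 0:
            pdf.loc[c, :] = np.nan
            pdf.loc[:, c] = np.nan
    return rdf, pdf


def descriptive_table(means: pd.DataFrame) -> pd.DataFrame:
    """Per-trait descriptive table over germplasm means (one row per trait:
    min / max / mean / std / cv, mirroring the usual variation-analysis
    layout)."""
    rows = []
    for col in means.columns:
        d = describe(means[col].to_numpy())
        rows.append({"trait": col, **d.as_dict()})
    return pd.DataFrame(rows).set_index("trait")
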