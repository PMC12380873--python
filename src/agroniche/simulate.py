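"""Synthetic inputs with known ground truth.

Everything downstream of the field-trial and niche-model stages is exercised
on data generated here: replicated germplasm-by-trait tables driven by a
latent yield axis, smooth environmental landscapes with a known logistic
suitability surface, presence points sampled from that surface, and mock
administrative region grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grids import Grid, Raster, RegionSet, Stack

__all__ = [
    "DEFAULT_TRAITS",
    "DEFAULT_EFFECT_SIGNS",
    "TraitSimConfig",
    "LandscapeSimConfig",
    "generate_trait_table",
    "generate_landscape",
    "generate_occurrences",
    "generate_regions",
    "default_orientations",
]

# Canonical trait roster: yields (HY, FY), stem/leaf/tiller architecture,
# and grain traits.  Grain filling competes with biomass, so thousand-kernel
# weight (TKW) and seed width (SW) load negatively on the latent yield axis;
# the hay-to-fresh ratio (HFR) is kept neutral.
DEFAULT_TRAITS: tuple[str, ...] = (
    "HFR", "PH", "RD", "SL", "RL", "SW", "LLf", "SLR", "LWf", "TSI",
    "LLfs", "LWfs", "SPL", "HYL", "TKW", "HY", "FY", "LAf", "HYS",
    "NTT", "LAfs", "NFT", "NVT",
)

DEFAULT_EFFECT_SIGNS: dict[str, int] = {
    **{t: 1 for t in DEFAULT_TRAITS},
    "TKW": -1,
    "SW": -1,
    "HFR": 0,
}


def default_orientations(effect_signs: dict[str, int] | None = None) -> dict[str, str]:
    """Benefit/cost orientation implied by the latent-yield effect signs."""
    signs = DEFAULT_EFFECT_SIGNS if effect_signs is None else effect_signs
    return {t: ("cost" if s < 0 else "benefit") for t, s in signs.items()}


@dataclass
class TraitSimConfig:
    """Configuration of the replicated trait-table generator."""

    n_germplasm: int = 40
    n_traits: int = 23
    n_reps: int = 10
    effect_signs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIGNS))
    germplasm_sd: float = 10.0
    replicate_sd: float = 2.0
    fertility_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_germplasm < 1 or self.n_traits < 1:
            raise ValueError("counts must be positive")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if not self.germplasm_sd > 0:
            raise ValueError("germplasm_sd must be positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        if not 0 <= self.fertility_fail_fraction < 1:
            raise ValueError("fertility_fail_fraction must lie in [0, 1)")

    @property
    def traits(self) -> list[str]:
        base = list(DEFAULT_TRAITS)
        if self.n_traits <= len(base):
            return base[: self.n_traits]
        extra = [f"X{i:02d}" for i in range(self.n_traits - len(base))]
        return base + extra


def generate_trait_table(cfg: TraitSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a long-format replicate table and its true latent ranking.

    Replicate value for germplasm g, trait t is
    ``baseline_t + sign_t * latent_g * scale_t + N(0, replicate_sd)`` with
    latent_g ~ N(0, germplasm_sd).  A fixed fraction of germplasms is
    flagged as not having completed the fertility period; rows are kept so
    the filtering step stays an explicit, testable operation.

    Returns (table, latent) where `latent` is indexed by germplasm id.
    """
    rng = np.random.default_rng(cfg.seed)
    traits = cfg.traits
    ids = [f"G{i + 1:02d}" for i in range(cfg.n_germplasm)]

    latent = rng.normal(0.0, cfg.germplasm_sd, size=cfg.n_germplasm)
    # per-trait baseline/scale: deterministic given the seed, all positive
    baselines = 50.0 + 8.0 * np.arange(len(traits))
    scales = 0.8 + 0.4 * rng.random(len(traits))
    signs = np.array([cfg.effect_signs.get(t, 0) for t in traits], dtype=float)

    n_fail = int(round(cfg.fertility_fail_fraction * cfg.n_germplasm))
    fail_idx = rng.choice(cfg.n_germplasm, size=n_fail, replace=False)
    completed = np.ones(cfg.n_germplasm, dtype=bool)
    completed[fail_idx] = False

    noise = rng.normal(0.0, cfg.replicate_sd, size=(cfg.n_germplasm, len(traits), cfg.n_reps))
    means = baselines[None, :] + signs[None, :] * latent[:, None] * scales[None, :]
    values = means[:, :, None] + noise

    g_idx, t_idx, r_idx = np.meshgrid(
        np.arange(cfg.n_germplasm), np.arange(len(traits)), np.arange(cfg.n_reps),
        indexing="ij",
    )
    table = pd.DataFrame(
        {
            "germplasm_id": np.array(ids)[g_idx.ravel()],
            "trait": np.array(traits)[t_idx.ravel()],
            "replicate": r_idx.ravel() + 1,
            "value": values.ravel(),
            "fertility_completed": completed[g_idx.ravel()],
        }
    )
    return table, pd.Series(latent, index=pd.Index(ids, name="germplasm_id"), name="latent")


@dataclass
class LandscapeSimConfig:
    """Configuration of the synthetic environmental-landscape generator."""

    extent: tuple[float, float, float, float] = (90.0, 100.0, 27.0, 37.0)  # xmin,xmax,ymin,ymax
    resolution: float = 0.25
    n_layers: int = 6
    smoothness: float = 3.0
    n_presence: int = 400
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"env01": 2.0, "env02": -1.5}
    )
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must be well-ordered (xmin<xmax, ymin<ymax)")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        if self.n_layers < 3:
            raise ValueError("need at least 3 layers")
        if not self.smoothness > 0:
            raise ValueError("smoothness must be positive")

    def grid(self) -> Grid:
        xmin, xmax, ymin, ymax = self.extent
        ncols = int(round((xmax - xmin) / self.resolution))
        nrows = int(round((ymax - ymin) / self.resolution))
        return Grid(ncols=ncols, nrows=nrows, xllcorner=xmin, yllcorner=ymin,
                    cellsize=self.resolution)


def _random_field(rng: np.random.Generator, grid: Grid, smoothness: float) -> np.ndarray:
    """Smooth random field: sum of seeded low-frequency sinusoids plus
    lightly smoothed noise, standardized to mean 0 / sd 1."""
    lon, lat = grid.center_mesh()
    xmin, xmax, ymin, ymax = grid.extent
    x = (lon - xmin) / (xmax - xmin)
    y = (lat - ymin) / (ymax - ymin)
    field_vals = np.zeros_like(x)
    n_waves = 8
    freq_scale = 2.0 / smoothness  # cycles across the extent
    for _ in range(n_waves):
        u, v = rng.normal(0.0, freq_scale, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        field_vals += amp * np.sin(2 * np.pi * (u * x + v * y) + phase)
    noise = rng.normal(0.0, 1.0, size=x.shape)
    # 3x3 box smoothing keeps the residual texture mild
    padded = np.pad(noise, 1, mode="edge")
    sm = sum(
        padded[i : i + x.shape[0], j : j + x.shape[1]] for i in range(3) for j in range(3)
    ) / 9.0
    field_vals += 0.15 * sm
    field_vals -= field_vals.mean()
    sd = field_vals.std()
    if sd > 0:
        field_vals /= sd
    return field_vals


def generate_landscape(cfg: LandscapeSimConfig) -> tuple[Stack, Raster]:
    """Simulate an environmental stack and its true logistic suitability."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    layers = {
        f"env{i + 1:02d}": _random_field(rng, grid, cfg.smoothness)
        for i in range(cfg.n_layers)
    }
    stack = Stack(grid, layers)
    eta = np.full((grid.nrows, grid.ncols), float(cfg.intercept))
    for name, coef in cfg.true_coefficients.items():
        if name not in layers:
            raise ValueError(f"true_coefficients references unknown layer {name!r}")
        eta = eta + coef * layers[name]
    truth = 1.0 / (1.0 + np.exp(-eta))
    return stack, Raster(truth, grid)


def generate_occurrences(
    truth: Raster, n_presence: int, seed: int, replace: bool = False
) -> pd.DataFrame:
    """Sample presence points with probability proportional to suitability.

    One lon/lat point per sampled cell center; duplicate cells only when
    `replace` is requested.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be positive")
    vals = truth.values
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("truth raster must lie in [0, 1]")
    flat = np.where(np.isfinite(vals), vals, 0.0).ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("truth raster has no positive suitability")
    positive = int((flat > 0).sum())
    if not replace and n_presence > positive:
        raise ValueError(
            f"n_presence={n_presence} exceeds the {positive} cells with positive suitability"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n_presence, replace=replace, p=flat / total)
    rows, cols = np.unravel_index(idx, vals.shape)
    lons = truth.grid.lon_centers()[cols]
    lats = truth.grid.lat_centers()[rows]
    return pd.DataFrame({"lon": lons, "lat": lats})


def generate_regions(
    extent: tuple[float, float, float, float], n_rows: int, n_cols: int
) -> RegionSet:
    """Tile the extent with an n_rows x n_cols grid of rectangular regions.

    Ids run SP01, SP02, ... row-major from the southwest corner.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    xmin, xmax, ymin, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must be well-ordered")
    dx = (xmax - xmin) / n_cols
    dy = (ymax - ymin) / n_rows
    ids, geoms = [], []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            k += 1
            ids.append(f"SP{k:02d}")
            geoms.append(box(xmin + j * dx, ymin + i * dy, xmin + (j + 1) * dx, ymin + (i + 1) * dy))
    return RegionSet(ids, geoms)
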