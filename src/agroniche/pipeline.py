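"""Pipeline driver: wires the synthetic-data, trait-evaluation, scoring,
path-analysis, niche-modelling, suitability-geography and adaptability
stages into one seeded, restartable run producing plain-text artifacts."""

from __future__ import annotations

import copy
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptability as adapt_mod
from . import geo as geo_mod
from . import path_analysis, scoring, sdm, simulate, traits
from .grids import RegionSet, read_ascii_grid, read_stack, write_ascii_grid, write_stack

__all__ = ["PipelineError", "default_config", "load_config", "run_pipeline"]

STAGES = ("simulate", "traits", "score", "path", "sdm", "geo", "adapt")


class PipelineError(RuntimeError):
    pass


def default_config(seed: int = 0) -> dict:
    """Demo configuration: small enough for a single-CPU run in minutes."""
    return {
        "seed": seed,
        "stages": {s: True for s in STAGES},
        "trait_sim": {
            "n_germplasm": 40,
            "n_traits": 23,
            "n_reps": 10,
            "germplasm_sd": 10.0,
            "replicate_sd": 2.0,
            "fertility_fail_fraction": 0.2,
        },
        "landscape": {
            "extent": [90.0, 100.0, 27.0, 37.0],
            "resolution": 0.25,
            "n_layers": 6,
            "smoothness": 3.0,
            "n_presence": 400,
            "true_coefficients": {"env01": 4.0, "env02": -3.0},
        },
        "regions": {"n_rows": 4, "n_cols": 5},
        "score": {
            "rho": 0.5,
            "variance_target": 0.60,
            "contribution_threshold": None,
            "linkage": "average",
            "cut_heights": {"hy": 40.0, "fy": 100.0, "membership": 0.2},
        },
        "path": {"ridge_k": "auto"},
        "sdm": {
            "repeats": 5,
            "train_fraction": 0.75,
            # presence-proportional sampling caps attainable AUC on the
            # synthetic truth; the library default stays at 0.75
            "auc_threshold": 0.70,
            "collinearity_threshold": 0.80,
        },
        "geo": {"breaks_k": 3},
        "adapt": {"permutations": 199, "trial_lon": 95.0, "trial_lat": 32.0},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config(int(user.get("seed", 0)))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' requires {path.name} produced by stage "
            f"'{stage}'; enable that stage or provide the file"
        )
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict, out: Path) -> dict:
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    tcfg = simulate.TraitSimConfig(seed=seed, **cfg["trait_sim"])
    table, latent = simulate.generate_trait_table(tcfg)
    table.to_csv(d / "traits.csv", index=False)
    latent.to_csv(d / "latent.csv")

    lkw = dict(cfg["landscape"])
    lkw["extent"] = tuple(lkw["extent"])
    n_presence = lkw.pop("n_presence")
    lcfg = simulate.LandscapeSimConfig(seed=seed + 1, n_presence=n_presence, **lkw)
    stack, truth = simulate.generate_landscape(lcfg)
    write_stack(stack, d / "env_current")
    write_ascii_grid(truth, d / "truth.asc")

    fut_cfg = simulate.LandscapeSimConfig(seed=seed + 2, n_presence=n_presence, **lkw)
    fut_stack, fut_truth = simulate.generate_landscape(fut_cfg)
    write_stack(fut_stack, d / "env_future")
    write_ascii_grid(fut_truth, d / "truth_future.asc")

    occ = simulate.generate_occurrences(truth, n_presence, seed=seed + 3)
    occ.to_csv(d / "occurrences.csv", index=False)

    regions = simulate.generate_regions(lcfg.extent, **cfg["regions"])
    regions.to_geojson(d / "regions.geojson")

    return {
        "n_germplasm": tcfg.n_germplasm,
        "n_presence": len(occ),
        "n_regions": len(regions),
        "grid": [lcfg.grid().nrows, lcfg.grid().ncols],
    }


def stage_traits(cfg: dict, out: Path) -> dict:
    d = out / "traits"
    d.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(_require(out / "simulate" / "traits.csv", "simulate", "traits"))
    filtered, n_removed = traits.filter_fertility(table)
    filtered.to_csv(d / "traits_filtered.csv", index=False)
    means = traits.trait_means(filtered)
    means.to_csv(d / "trait_means.csv")
    traits.descriptive_table(means).to_csv(d / "descriptive.csv")

    shannon = {}
    for gid, block in filtered.groupby("germplasm_id"):
        wide = block.pivot_table(index="replicate", columns="trait", values="value")
        total, _ = traits.shannon_trait_diversity(wide.clip(lower=0.0))
        shannon[gid] = total
    pd.Series(shannon, name="shannon").rename_axis("germplasm_id").to_csv(d / "shannon.csv")

    r, p = traits.pearson_matrix(means)
    r.to_csv(d / "pearson_r.csv")
    p.to_csv(d / "pearson_p.csv")
    return {"n_removed": n_removed, "n_retained": means.shape[0]}


def stage_score(cfg: dict, out: Path) -> dict:
    d = out / "score"
    d.mkdir(parents=True, exist_ok=True)
    sc = cfg["score"]
    means = pd.read_csv(
        _require(out / "traits" / "trait_means.csv", "traits", "score"),
        index_col="germplasm_id",
    )
    orientations = simulate.default_orientations()
    normalized = traits.min_max_normalize(means, orientations)
    wv = scoring.entropy_weights(normalized)
    pd.DataFrame(
        {"weight": wv.weights, "entropy": wv.entropy, "divergence": wv.divergence}
    ).to_csv(d / "weights.csv")

    r, _ = traits.pearson_matrix(means)
    gcfg = scoring.GreyConfig(rho=float(sc["rho"]))
    for target in ("HY", "FY"):
        factors = [c for c in means.columns if c not in ("HY", "FY")]
        fw = wv.weights[factors]
        fw = fw / fw.sum()
        res = scoring.grey_relational(
            normalized[target], normalized[factors], gcfg, factor_weights=fw
        )
        tbl = pd.DataFrame(
            {
                "correlation": r.loc[factors, target],
                "relevance": res.degrees,
                "rank": res.ranks,
            }
        ).rename_axis("factor").sort_values("rank")
        tbl.to_csv(d / f"grey_{target}.csv")

    contrib = scoring.pca_contributions(
        normalized,
        variance_target=float(sc["variance_target"]),
        contribution_threshold=sc.get("contribution_threshold"),
    )
    contrib.to_csv(d / "pca_contributions.csv")
    selected = list(contrib.index[contrib["selected"]])

    member = scoring.membership_scores(means[selected], orientations)
    member.scores.rename_axis("germplasm_id").to_csv(d / "membership.csv")

    cuts = sc["cut_heights"]
    labels = pd.DataFrame(
        {
            "hy_class": scoring.hcluster_cut(means["HY"], float(cuts["hy"]), sc["linkage"]),
            "fy_class": scoring.hcluster_cut(means["FY"], float(cuts["fy"]), sc["linkage"]),
            "membership_class": scoring.hcluster_cut(
                member.scores, float(cuts["membership"]), sc["linkage"]
            ),
        }
    ).rename_axis("germplasm_id")
    labels.to_csv(d / "clusters.csv")
    return {
        "explained_variance": contrib.attrs["explained_variance"],
        "n_selected": len(selected),
        "membership_range": [float(member.scores.min()), float(member.scores.max())],
    }


def stage_path(cfg: dict, out: Path) -> dict:
    d = out / "path"
    d.mkdir(parents=True, exist_ok=True)
    means = pd.read_csv(
        _require(out / "traits" / "trait_means.csv", "traits", "path"),
        index_col="germplasm_id",
    )
    k = cfg["path"]["ridge_k"]
    summary = {}
    # HY may be routed through FY and the dry-matter components; FY may not.
    predictor_sets = {
        "HY": [c for c in means.columns if c != "HY"],
        "FY": [c for c in means.columns if c not in ("FY", "HY", "HFR", "HYS", "HYL")],
    }
    for target, predictors in predictor_sets.items():
        res = path_analysis.ridge_path(means[predictors], means[target], k=k)
        pd.DataFrame(
            {"direct": res.direct, "total": res.total, "r_with_y": res.r_with_y}
        ).rename_axis("trait").to_csv(d / f"path_{target}.csv")
        res.indirect.rename_axis("trait").to_csv(d / f"indirect_{target}.csv")
        summary[target] = {"k": res.k, "r_squared": res.r_squared,
                           "residual": res.residual}
    return summary


def stage_sdm(cfg: dict, out: Path) -> dict:
    d = out / "sdm"
    d.mkdir(parents=True, exist_ok=True)
    sc = cfg["sdm"]
    seed = int(cfg["seed"])
    sim_dir = out / "simulate"
    stack = read_stack(_require(sim_dir / "env_current" / "manifest.yaml", "simulate", "sdm"))
    occ = pd.read_csv(_require(sim_dir / "occurrences.csv", "simulate", "sdm"))

    cleaned, report = sdm.clean_occurrences(occ, stack.grid.extent)
    thinned = sdm.rarefy(cleaned, stack.grid.cellsize, seed=seed + 10)
    filtered, dropped = sdm.collinearity_filter(stack, float(sc["collinearity_threshold"]))
    background = sdm.pseudo_absences(filtered, thinned, seed=seed + 11)
    model = sdm.fit_ensemble(
        thinned,
        background,
        filtered,
        repeats=int(sc["repeats"]),
        train_fraction=float(sc["train_fraction"]),
        auc_threshold=float(sc["auc_threshold"]),
        seed=seed + 12,
    )
    write_ascii_grid(model.consensus, d / "consensus_current.asc")
    write_stack(filtered, d / "env_filtered")

    fut_stack = read_stack(sim_dir / "env_future" / "manifest.yaml").subset(filtered.names)
    write_ascii_grid(model.predict(fut_stack), d / "consensus_future.asc")
    write_stack(fut_stack, d / "env_future_filtered")

    importance = sdm.variable_importance(model, filtered, seed=seed + 13)
    importance.rename_axis("variable").to_csv(d / "importance.csv")
    model.learner_correlations.rename_axis("learner").to_csv(d / "learner_correlations.csv")

    _write_json(
        {
            "cleaning": report,
            "n_thinned": len(thinned),
            "dropped_layers": dropped,
            "learner_auc": model.learner_auc,
            "weights": model.weights,
            "ensemble": model.metrics.as_dict(),
        },
        d / "metrics.json",
    )
    return {"ensemble_auc": model.metrics.auc, "n_layers": len(filtered)}


def stage_geo(cfg: dict, out: Path) -> dict:
    d = out / "geo"
    d.mkdir(parents=True, exist_ok=True)
    k = int(cfg["geo"]["breaks_k"])
    regions = RegionSet.from_geojson(
        _require(out / "simulate" / "regions.geojson", "simulate", "geo")
    )
    summaries = {}
    classmaps = {}
    for period in ("current", "future"):
        rast = read_ascii_grid(
            _require(out / "sdm" / f"consensus_{period}.asc", "sdm", "geo")
        )
        breaks = geo_mod.jenks_breaks(rast.values[rast.mask], k=k)
        cmap = geo_mod.classify(rast, breaks)
        classmaps[period] = cmap
        write_ascii_grid(cmap, d / f"class_{period}.asc")
        summary = geo_mod.regional_summary(cmap, regions)
        summary.to_csv(d / f"areas_{period}.csv", index=False)
        summaries[period] = summary

    suitable = list(range(1, k))
    c1 = geo_mod.class_centroid(classmaps["current"], suitable)
    c2 = geo_mod.class_centroid(classmaps["future"], suitable)
    shift = geo_mod.centroid_shift(c1, c2)
    _write_json(shift.as_dict(), d / "centroid_shift.json")

    change = geo_mod.change_summary(summaries["current"], summaries["future"])
    change.to_csv(d / "change_summary.csv", index=False)
    return {"centroid_shift_km": shift.distance_km, "direction": shift.direction}


def stage_adapt(cfg: dict, out: Path) -> dict:
    d = out / "adapt"
    d.mkdir(parents=True, exist_ok=True)
    ac = cfg["adapt"]
    seed = int(cfg["seed"])
    suit = read_ascii_grid(_require(out / "sdm" / "consensus_current.asc", "sdm", "adapt"))
    stack = read_stack(_require(out / "sdm" / "env_filtered" / "manifest.yaml", "sdm", "adapt"))
    classmap = read_ascii_grid(_require(out / "geo" / "class_current.asc", "geo", "adapt"))
    regions = RegionSet.from_geojson(
        _require(out / "simulate" / "regions.geojson", "simulate", "adapt")
    )
    membership = pd.read_csv(
        _require(out / "score" / "membership.csv", "score", "adapt"),
        index_col="germplasm_id",
    )["membership_score"]

    profiles = adapt_mod.region_profiles(suit, stack, regions, classmap)
    profiles.to_csv(d / "profiles.csv")

    best, scores = adapt_mod.optimal_dissimilarity(profiles)
    _write_json(
        {"chosen": best, "rank_correlations": scores.to_dict()},
        d / "dissimilarity.json",
    )

    feat_cols = [c for c in profiles.columns if c.startswith("env_")]
    from scipy.spatial.distance import pdist, squareform

    D_env = squareform(adapt_mod._CANDIDATES[best](profiles[feat_cols].to_numpy(float)))
    D_suit = squareform(pdist(profiles[["mean_suitability"]].to_numpy(float), "cityblock"))
    mres = adapt_mod.mantel(
        D_env, D_suit, permutations=int(ac["permutations"]), seed=seed + 20
    )
    _write_json(
        {
            "statistic": mres.statistic,
            "p_value": mres.p_value,
            "permutations": mres.permutations,
            "exact": mres.exact,
            "method": mres.method,
        },
        d / "mantel.json",
    )

    trial = pd.Series(
        stack.sample(np.array([float(ac["trial_lon"])]), np.array([float(ac["trial_lat"])]))[0],
        index=[f"env_{n}" for n in stack.names],
    )
    result = adapt_mod.adaptability_matrix(
        membership, profiles, trial, permutations=int(ac["permutations"]), seed=seed + 21
    )
    result.matrix.to_csv(d / "adaptability.csv", index=False)
    adapt_mod.region_similarity_matrix(profiles).rename_axis("region_id").to_csv(
        d / "region_correlation.csv"
    )
    result.suitable_area.rename_axis("germplasm_id").to_csv(d / "suitable_area.csv")
    return {
        "mantel_r": mres.statistic,
        "mantel_p": mres.p_value,
        "n_high": int((result.matrix["class"] == "high").sum()),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "traits": stage_traits,
    "score": stage_score,
    "path": stage_path,
    "sdm": stage_sdm,
    "geo": stage_geo,
    "adapt": stage_adapt,
}


def run_pipeline(cfg: dict, outdir: str | Path, verbose: bool = False) -> dict:
    """Run the enabled stages in order; abort on the first failure.

    Earlier stages' outputs are preserved on failure.  Returns the summary
    dict that is also written to run_summary.json.
    """
    cfg = copy.deepcopy(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.get("seed", 0), "stages": {}}
    for stage in STAGES:
        if not cfg["stages"].get(stage, False):
            continue
        if verbose:
            print(f"[agroniche] running stage {stage}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary["stages"][stage] = _STAGE_FUNCS[stage](cfg, out)
    _write_json(summary, out / "run_summary.json")
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return summary
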