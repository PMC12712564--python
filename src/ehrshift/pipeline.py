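"""End-to-end orchestration: simulate/ingest → characterize → model → associate.

A single :class:`RunConfig` drives the four phases of the study design:

A. data preparation (simulate a scenario or ingest admission files, harmonize
   codes into chapters, one-hot encode, batch by year);
B. unsupervised shift characterization (univariate DTHs; FAMD reduction, per
   year KDE maps, IGT projections; temporal clustering of the data IGT);
C. predictive modelling (yearly stratified splits, shared hyperparameters,
   Youden thresholds, interyear evaluation matrices for six metrics);
D. association (per-metric performance embeddings clustered and tested
   against the data partition with Fisher exact tests and FDR adjustment).

Every artifact is written under the output directory and listed, with a
SHA-256 hash, in ``manifest.json``; one master seed fans out to per-stage
seeds through a stable hash so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import dth as dth_mod
from . import igt as igt_mod
from . import latent, models, synthetic
from .errors import ConfigurationError, EhrShiftError
from .ingest import (
    batch_by_year,
    harmonize_codes,
    load_code_map,
    read_admissions,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "stage_seed", "characterize_data_shift"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{seed}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Serializable description of one full study run."""

    outdir: str
    seed: int = 0
    # input: either a synthetic scenario kind or file paths
    scenario_kind: str | None = "combined"
    n_per_year: int = 2000
    admissions_path: str | None = None
    codes_path: str | None = None
    mapping_path: str | None = None
    # characterization
    reduction_dims: int = 3
    grid_size: int | None = None
    dth_alpha: float = dth_mod.DEFAULT_ALPHA
    # modelling
    algorithm: str = "random_forest"
    model_params: dict | None = None
    grid_search: bool = False
    metrics: tuple[str, ...] = models.METRICS
    # association
    methods: tuple[str, ...] = ("hierarchical", "kmeans")
    k: int = 2
    dissimilarity_mode: str = "average"
    make_plots: bool = False

    def __post_init__(self) -> None:
        file_input = self.admissions_path is not None
        if file_input and (self.codes_path is None):
            raise ConfigurationError("file input requires both admissions and codes")
        if not file_input and self.scenario_kind is None:
            raise ConfigurationError("either a scenario kind or file paths required")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        d["methods"] = list(self.methods)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["metrics"] = tuple(d["metrics"])
        d["methods"] = tuple(d["methods"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def characterize_data_shift(
    batches: list[tuple[int, pd.DataFrame]],
    features: pd.DataFrame,
    reduction_dims: int = 3,
    grid_size: int | None = None,
) -> dict:
    """Phase B core: FAMD + per-year KDE + IGT, marginal and class-combined.

    Returns the fitted reduction, the full-cohort density map and its IGT
    (covariate-shift view), and the renormalized class-conditional combined
    map with its IGT (concept-shift view).
    """
    reduction = latent.fit_mixed_reduction(features, d=reduction_dims)
    years = features["year"].to_numpy()
    full_map = latent.kde_density_map(reduction, years, grid_size=grid_size)
    igt_full = igt_mod.mds_embed(igt_mod.js_dissimilarity(full_map), k=3)

    outcome = features["outcome"].to_numpy()
    class_maps, weights = {}, {}
    prior = dth_mod.prior_dth(batches)
    for c in (0, 1):
        mass, bandwidths = _reevaluate_on_grid(
            reduction.coords[outcome == c], years[outcome == c], full_map
        )
        # class maps share the full-cohort grid so they can be mixed
        class_maps[c] = latent.DensityMap(
            axes=full_map.axes, grid=full_map.grid, years=list(full_map.years),
            mass=mass, bandwidths=bandwidths,
        )
        weights[c] = prior.probs[prior.support.index(c), :]
    combined = latent.combine_conditional_maps(class_maps, weights)
    igt_combined = igt_mod.mds_embed(igt_mod.js_dissimilarity(combined), k=3)
    return {
        "reduction": reduction,
        "density_map": full_map,
        "igt_covariate": igt_full,
        "class_maps": class_maps,
        "combined_map": combined,
        "igt_conditional": igt_combined,
        "prior": prior,
    }


def _reevaluate_on_grid(
    coords: np.ndarray, years: np.ndarray, reference: latent.DensityMap
) -> tuple[np.ndarray, np.ndarray]:
    """KDE mass for subset coordinates evaluated on an existing shared grid."""
    grid = reference.grid
    d = grid.shape[1]
    mass = np.empty((grid.shape[0], len(reference.years)))
    bandwidths = np.empty((len(reference.years), d))
    for t, year in enumerate(reference.years):
        pts = coords[years == year]
        if pts.ndim == 1:
            pts = pts[:, None]
        h = latent._scott_bandwidth(pts)
        bandwidths[t] = h
        dens = latent._product_kde_mass(pts, reference.axes, h)
        mass[:, t] = dens / dens.sum()
    return mass, bandwidths


def run_study(config: RunConfig) -> dict:
    """Execute phases A–D, writing every artifact and a hashed manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.to_json()), "artifacts": {},
                      "stage_seeds": {}, "log": []}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(Path(path))
        }

    def fail(stage: str, exc: Exception):
        manifest["log"].append(f"stage {stage} failed: {exc}")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise EhrShiftError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "config.json").write_text(config.to_json())
    record("config", outdir / "config.json")

    # ---- phase A: data -------------------------------------------------
    stage = "ingest"
    try:
        if config.admissions_path is not None:
            if config.mapping_path is None:
                raise ConfigurationError("file input requires mapping_path")
            table = read_admissions(config.admissions_path, config.codes_path)
            code_map = load_code_map(config.mapping_path)
        else:
            sim_seed = stage_seed(config.seed, "simulate")
            manifest["stage_seeds"]["simulate"] = sim_seed
            scenario = synthetic.default_scenario(
                config.scenario_kind, n_per_year=config.n_per_year, seed=sim_seed
            )
            table = synthetic.generate_cohort(scenario)
            paths = synthetic.write_cohort(table, scenario, outdir / "cohort")
            for k, v in paths.items():
                record(f"cohort/{k}", Path(v))
            map_path = outdir / "cohort" / "code_map.csv"
            synthetic.default_code_map().to_csv(map_path, index=False)
            record("cohort/code_map", map_path)
            code_map = load_code_map(map_path)
        features = harmonize_codes(table, code_map)
        batches = batch_by_year(features)
        msg = f"ingest: {len(features)} admissions, {len(batches)} yearly batches"
        manifest["log"].append(msg)
        logger.info(msg)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # ---- phase B: shift characterization -------------------------------
    stage = "characterize"
    try:
        char = characterize_data_shift(
            batches, features,
            reduction_dims=config.reduction_dims, grid_size=config.grid_size,
        )
        dth_dir = outdir / "dth"
        dth_dir.mkdir(exist_ok=True)
        char["prior"].write(dth_dir / "prior.csv")
        record("dth/prior", dth_dir / "prior.csv")
        chapter_cols = [
            c for c in features.columns if c.startswith("chapter::")
        ]
        conditionals = {}
        for col in chapter_cols:
            m = dth_mod.marginal_dth(batches, col, alpha=config.dth_alpha)
            m.write(dth_dir / f"marginal_{col.split('::')[1][:30]}.csv")
        for c in (0, 1):
            conditionals[c] = dth_mod.conditional_dth(
                batches, chapter_cols[0], c, alpha=config.dth_alpha
            )
        posterior = dth_mod.posterior_dth(conditionals, char["prior"])
        posterior.write(dth_dir / "posterior_example.csv")
        record("dth/posterior_example", dth_dir / "posterior_example.csv")

        char["igt_covariate"].write(outdir / "igt_covariate.csv")
        record("igt/covariate", outdir / "igt_covariate.csv")
        char["igt_conditional"].write(outdir / "igt_conditional.csv")
        record("igt/conditional", outdir / "igt_conditional.csv")

        data_partitions = {}
        for method in config.methods:
            fn = (
                assoc.hierarchical_partition
                if method == "hierarchical"
                else assoc.kmeans_partition
            )
            part = fn(char["igt_covariate"], k=config.k)
            data_partitions[method] = part
            p = outdir / f"data_partition_{method}.json"
            p.write_text(part.to_json())
            record(f"partition/{method}", p)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- phase C: models ----------------------------------------------
    stage = "models"
    try:
        model_seed = stage_seed(config.seed, "models")
        manifest["stage_seeds"]["models"] = model_seed
        splits = models.make_splits(batches, seed=model_seed)
        if config.grid_search:
            params, grid_table = models.select_hyperparameters(
                batches, splits, config.algorithm, seed=model_seed
            )
            grid_table.to_csv(outdir / "grid_scores.csv", index=False)
            record("grid_scores", outdir / "grid_scores.csv")
        else:
            params = config.model_params or {"n_estimators": 100, "max_depth": 6}
        mset = models.fit_models(
            batches, splits, config.algorithm, params, seed=model_seed
        )
        (outdir / "model_set.json").write_text(json.dumps(mset.metadata(), indent=2))
        record("model_set", outdir / "model_set.json")
        eval_matrices = models.interyear_evaluations(
            mset, batches, splits, config.metrics
        )
        for metric, em in eval_matrices.items():
            p = outdir / f"eval_{metric}.csv"
            em.write(p)
            record(f"eval/{metric}", p)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- phase D: association ------------------------------------------
    stage = "associate"
    try:
        rows = []
        for method, part in data_partitions.items():
            results = assoc.associate(
                part, eval_matrices, method=method, k=config.k,
                dissimilarity_mode=config.dissimilarity_mode,
            )
            for r in results:
                rows.append(
                    {
                        "metric": r.metric,
                        "method": r.method,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "table": r.table.counts.tolist(),
                    }
                )
        assoc_table = pd.DataFrame(rows)
        assoc_table.to_csv(outdir / "association.csv", index=False)
        record("association", outdir / "association.csv")
        manifest["association"] = rows
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    if config.make_plots:
        from . import plots

        plots.plot_igt(char["igt_covariate"], outdir / "igt_covariate.png")
        record("plot/igt_covariate", outdir / "igt_covariate.png")
        plots.plot_eval_matrix(
            eval_matrices[config.metrics[0]], outdir / "eval_heatmap.png"
        )
        record("plot/eval_heatmap", outdir / "eval_heatmap.png")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
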