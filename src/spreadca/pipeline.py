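"""End-to-end synthetic pipeline: landscape -> SDM -> dispersal -> outputs.

Mirrors the study workflow on a generated world: build a landscape with
known truth, sample and thin occurrences, place pseudo-absences, select
covariates, fit and evaluate the suitability model, project it over the
grid (optionally downscaling by kriging), rasterize the initial
distribution, optionally calibrate LDD parameters against forward-
simulated "observed" spread, and run the replicated dispersal simulation.
Every artifact is written under the output directory, and a JSON manifest
records the full config, every derived seed, and a SHA-256 hash of every
artifact, so a rerun with the same config reproduces the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import ca, calibration, habitat, kriging, occurrences, synthetic
from .config import PipelineConfig
from .errors import PipelineStageError
from .raster import RasterLayer, write_ascii_grid

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(cfg.model_dump_json(by_alias=True)),
                      "stages": {}, "artifacts": {}}
    artifacts: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                value = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc
            manifest["stages"][name] = "ok"
            return value
        return wrap

    # 1. synthetic landscape
    def _synth():
        bundle = synthetic.gen_landscape(cfg.synth.to_spec(seed=cfg.seed))
        synthetic.write_bundle(bundle, out / "landscape")
        artifacts.extend(sorted((out / "landscape").glob("*")))
        return bundle
    bundle = stage("synth")(_synth)

    # 2. occurrences: sample from truth, thin, add pseudo-absences
    def _occ():
        occ = synthetic.gen_occurrences(bundle.suitability_truth,
                                        n=cfg.n_occurrences, seed=cfg.seed + 1)
        thin_cfg = cfg.thinning.to_config(seed=cfg.seed + 2)
        thinned = occurrences.thin_occurrences(occ, thin_cfg)
        mask = bundle.landcover.with_values(
            np.ones(bundle.landcover.shape, dtype=np.int64))
        pas = occurrences.sample_pseudo_absences(mask, thinned, thin_cfg)
        combined = thinned.concat(pas)
        combined.write_csv(out / "occurrences.csv")
        artifacts.append(out / "occurrences.csv")
        return combined
    occ = stage("occurrences")(_occ)

    # 3. suitability model
    def _sdm():
        table = habitat.extract_covariates(occ, bundle.covariates)
        sel = habitat.select_variables(table, cfg.selection.to_config())
        cols = sel.kept + [habitat.LABEL_COLUMN]
        train, test = habitat.split_train_test(table[cols], ratio=0.7,
                                               seed=cfg.seed + 3)
        model = habitat.fit_suitability(train, n_trees=cfg.n_trees,
                                        seed=cfg.seed + 4)
        report = habitat.evaluate_model(test[habitat.LABEL_COLUMN],
                                        model.predict(test), seed=cfg.seed + 3)
        (out / "sdm_eval.json").write_text(json.dumps(
            {"selected": sel.kept, "selection_log": sel.log,
             **report.as_dict()}, indent=2, default=float))
        artifacts.append(out / "sdm_eval.json")
        model.save(out / "sdm_model.joblib")
        return model, report
    model, report = stage("sdm")(_sdm)
    manifest["sdm_eval"] = report.as_dict()

    # 4. projected suitability (+ optional kriging downscale)
    def _project():
        suit = habitat.project_suitability(model, bundle.covariates)
        if cfg.downscale_target_cell is not None:
            suit = kriging.downscale_kriging(suit, cfg.downscale_target_cell)
        write_ascii_grid(suit, out / "suitability.asc")
        artifacts.append(out / "suitability.asc")
        return suit
    suit = stage("project")(_project)

    landcover = bundle.landcover
    stack = ca.SuitabilityStack(periods=[(0, suit)],
                                invasibility_threshold=cfg.invasibility_threshold)

    # 5. initial distribution from the first presences
    def _init():
        pres = occ.presences()
        pts = np.column_stack([pres.x, pres.y])[: cfg.n_init_points]
        grid = ca.CellStateGrid.from_landcover(landcover)
        init, n_regions = ca.build_initial_distribution(
            pts, grid, buffer_radius=cfg.init_buffer_radius,
            merge_dist=cfg.init_merge_dist,
            maturity_age=cfg.dispersal.maturity_age)
        write_ascii_grid(init, out / "initial_distribution.asc")
        artifacts.append(out / "initial_distribution.asc")
        manifest["n_init_regions"] = n_regions
        return init
    init = stage("initial_distribution")(_init)

    # 6. optional LDD calibration against forward-simulated observed spread
    if cfg.calibrate:
        def _calibrate():
            base = cfg.dispersal.to_params(seed=cfg.seed + 5)
            grid = calibration.default_param_grid(base)
            observed = synthetic.gen_observed_spread(
                bundle, init, base, years=cfg.calibration_horizon,
                seed=cfg.seed + 6,
                invasibility_threshold=cfg.invasibility_threshold)
            table = calibration.calibrate_ldd(
                grid, init, stack, landcover, observed,
                horizon_years=cfg.calibration_horizon, seed=cfg.seed + 7)
            letters = calibration.tukey_grouping(table)
            table.summary["letters"] = [letters[l] for l in table.summary["param_label"]]
            table.write_csv(out / "calibration_scores.csv",
                            out / "calibration_summary.csv")
            artifacts.extend([out / "calibration_scores.csv",
                              out / "calibration_summary.csv"])
            manifest["calibration"] = {"best_label": table.best_label,
                                       "labels": list(grid)}
            return table
        stage("calibrate")(_calibrate)

    # 7. replicated dispersal simulation
    def _simulate():
        params = cfg.dispersal.to_params(seed=cfg.seed + 8)
        result = ca.run_simulation(init, stack, landcover, params,
                                   horizon_years=cfg.horizon_years)
        suit_mask = suit.with_values(
            (suit.values >= cfg.invasibility_threshold).astype(np.int64))
        pct = ca.percent_colonized(result, suit_mask)
        pct.to_csv(out / "percent_colonized.csv", index=False)
        artifacts.append(out / "percent_colonized.csv")
        write_ascii_grid(result.final_occupancy(0), out / "final_occupancy_rep0.asc")
        artifacts.append(out / "final_occupancy_rep0.asc")
        manifest["final_pct_colonized_mean"] = float(pct["mean"].iloc[-1])
        return result
    stage("simulate")(_simulate)

    manifest["artifacts"] = {str(p.relative_to(out)): _sha256(p)
                             for p in artifacts if p.is_file()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
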