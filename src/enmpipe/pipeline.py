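"""End-to-end pipeline: generate -> screen -> tune -> fit -> project ->
classify -> change -> niche -> reserve, with per-stage seeds, provenance
sidecars, and a manifest of every artifact written.

One global seed deterministically derives a per-stage seed by hashing the
stage name, so stages are reproducible independently and the whole run is
byte-reproducible under an identical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, niche, reserve, screening, synthetic, tuning
from .geodata import (EnvStack, clean_occurrences, occurrence_cells,
                      save_occurrences, write_grid)
from .maxent import build_features, fit_maxent, predict, sample_background

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # synthetic study system
    n_rows: int = 60
    n_cols: int = 60
    n_vars: int = 12
    n_presences: int = 200
    noise_fraction: float = 0.1
    scenario_severities: dict[str, float] = field(
        default_factory=lambda: {"ssp126": 0.5, "ssp245": 1.0, "ssp585": 2.0})
    # screening
    r_max: float = 0.7
    vif_max: float = 5.0
    # tuning / fitting
    rms: tuple[float, ...] = tuning.DEFAULT_RMS
    fcs: tuple[str, ...] = tuning.DEFAULT_FCS
    n_replicates: int = 10
    train_fraction: float = 0.75
    background_n: int = 10000
    n_knots: int = 10
    max_iterations: int = 10000
    skip_tuning: bool = False
    fallback_fc: str = "LQ"
    fallback_rm: float = 1.0
    # classification / change
    thresholds: tuple[float, float, float] = dynamics.DEFAULT_THRESHOLDS
    # reserve
    target_fraction: float = 0.30
    spf: float = 100.0
    blm: float = 25000.0
    n_runs: int = 100
    pu_size_km: float = 25.0

    def validate(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (0 < t1 < t2 < t3 < 1):
            raise ValueError("thresholds must be strictly increasing in (0,1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must be in (0,1]")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0,1)")
        if self.n_presences < 8:
            raise ValueError("n_presences must be at least 8")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []

    def _record(self, stage: str, path: Path, params: dict) -> None:
        entry = {"stage": stage, "path": str(path), "seed": stage_seed(self.config.seed, stage),
                 "params": params, "sha256_16": _digest(path)}
        self.manifest.append(entry)
        sidecar = path.with_suffix(path.suffix + ".prov.json")
        sidecar.write_text(json.dumps(entry, indent=2, default=str) + "\n")

    def run(self) -> dict:
        cfg = self.config
        t_start = time.time()
        results: dict = {}

        # -- generate ------------------------------------------------------
        logger.info("stage generate")
        syn = synthetic.SyntheticConfig(
            n_rows=cfg.n_rows, n_cols=cfg.n_cols, n_vars=cfg.n_vars,
            n_presences=cfg.n_presences, noise_fraction=cfg.noise_fraction,
            seed=stage_seed(cfg.seed, "generate"))
        stack = synthetic.make_env_stack(syn)
        truth = synthetic.true_suitability(stack, syn.true_coefficients, syn.intercept)
        occ_raw = synthetic.sample_occurrences(
            truth, syn.n_presences, seed=stage_seed(cfg.seed, "occurrences"),
            noise_fraction=syn.noise_fraction)
        occ = clean_occurrences(occ_raw, stack.grid)
        futures = {
            name: synthetic.make_future_stack(
                stack, synthetic.default_future_deltas(syn, severity=sev))
            for name, sev in cfg.scenario_severities.items()}
        p_truth = self.out / "true_suitability.asc"
        write_grid(truth, p_truth)
        self._record("generate", p_truth, {"n_presences": len(occ_raw),
                                           "n_cleaned": len(occ)})
        p_occ = self.out / "occurrences.csv"
        save_occurrences(occ, p_occ)
        self._record("generate", p_occ, {})
        results["n_occurrences"] = len(occ)

        # -- screen --------------------------------------------------------
        logger.info("stage screen")
        report = screening.screen_variables(stack, occ, r_max=cfg.r_max,
                                            vif_max=cfg.vif_max)
        kept_stack = EnvStack({n: stack[n] for n in report.kept})
        kept_futures = {name: EnvStack({n: fs[n] for n in report.kept})
                        for name, fs in futures.items()}
        p_corr = self.out / "screening_correlation.csv"
        report.correlation.to_csv(p_corr)
        self._record("screen", p_corr, {"kept": report.kept})
        (self.out / "screening_summary.txt").write_text(report.summary() + "\n")
        results["n_kept_variables"] = len(report.kept)

        # -- tune ----------------------------------------------------------
        if cfg.skip_tuning:
            best_fc, best_rm = cfg.fallback_fc, cfg.fallback_rm
            results["tuning"] = "skipped"
        else:
            logger.info("stage tune")
            table, best = tuning.tune_grid(
                occ, kept_stack, rms=cfg.rms, fcs=cfg.fcs,
                seed=stage_seed(cfg.seed, "tune"),
                n_replicates=cfg.n_replicates,
                train_fraction=cfg.train_fraction,
                background_n=cfg.background_n, n_knots=cfg.n_knots,
                max_iterations=cfg.max_iterations)
            p_tab = self.out / "tuning_table.csv"
            table.to_csv(p_tab, index=False)
            self._record("tune", p_tab, {"best_fc": best.fc, "best_rm": best.rm})
            best_fc, best_rm = best.fc, best.rm
            results["best_fc"] = best.fc
            results["best_rm"] = best.rm
            results["best_auc_train"] = best.auc_train_mean

        # -- fit + project -------------------------------------------------
        logger.info("stage fit")
        bg = sample_background(kept_stack, n=cfg.background_n,
                               seed=stage_seed(cfg.seed, "background"))
        spec = build_features(kept_stack, classes=best_fc, n_knots=cfg.n_knots,
                              background_cells=bg)
        cells = occurrence_cells(occ, kept_stack.grid)
        model = fit_maxent(cells, bg, kept_stack, spec, rm=best_rm,
                           max_iterations=cfg.max_iterations)
        p_model = self.out / "model.txt"
        p_model.write_text(model.to_text())
        self._record("fit", p_model, {"fc": best_fc, "rm": best_rm,
                                      "k": model.n_parameters})
        current = predict(model, kept_stack, output_kind="logistic")
        p_cur = self.out / "suitability_current.asc"
        write_grid(current.grid, p_cur)
        self._record("project", p_cur, {"scenario": "current"})
        future_maps = {}
        for name, fs in kept_futures.items():
            sm = predict(model, fs, output_kind="logistic")
            future_maps[name] = sm
            p = self.out / f"suitability_{name}.asc"
            write_grid(sm.grid, p)
            self._record("project", p, {"scenario": name})

        # -- classify + change + centroid ---------------------------------
        logger.info("stage change")
        classified = dynamics.classify_suitability(current, cfg.thresholds)
        areas = dynamics.area_by_class(classified)
        cur_bin = dynamics.binarize(current, cfg.thresholds[0])
        rows = []
        cur_centroid = dynamics.centroid(cur_bin) if (cur_bin.values == 1).any() else None
        for name, sm in future_maps.items():
            fut_bin = dynamics.binarize(sm, cfg.thresholds[0])
            cmap, stats = dynamics.change_matrix(cur_bin, fut_bin)
            p = self.out / f"change_{name}.asc"
            write_grid(cmap, p)
            self._record("change", p, {"scenario": name})
            row = {"scenario": name, "gain_km2": stats.gain_area,
                   "loss_km2": stats.loss_area, "stable_km2": stats.stable_area,
                   "current_km2": stats.current_area,
                   "percent_gain": stats.percent_gain,
                   "percent_loss": stats.percent_loss,
                   "range_change": stats.range_change}
            if cur_centroid is not None and (fut_bin.values == 1).any():
                fc_ = dynamics.centroid(fut_bin)
                row["centroid_lon"] = fc_.longitude
                row["centroid_lat"] = fc_.latitude
                row["migration_m"] = dynamics.geodesic_distance(cur_centroid, fc_)
            rows.append(row)
        p_change = self.out / "change_stats.csv"
        pd.DataFrame(rows).to_csv(p_change, index=False)
        self._record("change", p_change, {})
        results["current_suitable_km2"] = areas.total_suitable
        results["change"] = rows

        # -- niche ---------------------------------------------------------
        logger.info("stage niche")
        p_cur_dens = niche.normalize_density(current)
        niche_rows = []
        for name, sm in future_maps.items():
            d = niche.schoener_d(p_cur_dens, niche.normalize_density(sm))
            nb = niche.niche_breadth(sm)
            niche_rows.append({"scenario": name, "d_vs_current": d,
                               "b1": nb.b1, "b2": nb.b2})
        nb0 = niche.niche_breadth(current)
        niche_rows.insert(0, {"scenario": "current", "d_vs_current": 1.0,
                              "b1": nb0.b1, "b2": nb0.b2})
        p_niche = self.out / "niche_metrics.csv"
        pd.DataFrame(niche_rows).to_csv(p_niche, index=False)
        self._record("niche", p_niche, {})
        results["niche"] = niche_rows

        # -- reserve -------------------------------------------------------
        logger.info("stage reserve")
        pus = reserve.build_planning_units(cur_bin, pu_size_km=cfg.pu_size_km)
        rcfg = reserve.ReserveConfig(target_fraction=cfg.target_fraction,
                                     spf=cfg.spf, blm=cfg.blm,
                                     n_runs=cfg.n_runs,
                                     seed=stage_seed(cfg.seed, "reserve"))
        sol = reserve.run_repeats(pus, rcfg)
        p_sol = self.out / "reserve_solution.csv"
        pd.DataFrame({
            "unit_id": pus.ids,
            "cost": [u.cost for u in pus.units],
            "selected": [int(i in sol.selected) for i in pus.ids],
            "selection_frequency": [sol.selection_frequency.get(i, 0)
                                    for i in pus.ids],
        }).to_csv(p_sol, index=False)
        self._record("reserve", p_sol, {"total": sol.components.total,
                                        "n_selected": len(sol.selected)})
        results["reserve_total"] = sol.components.total
        results["reserve_n_selected"] = len(sol.selected)

        # -- manifest ------------------------------------------------------
        p_manifest = self.out / "manifest.json"
        p_manifest.write_text(json.dumps(
            {"config": asdict(self.config), "elapsed_s": time.time() - t_start,
             "artifacts": self.manifest}, indent=2, default=str) + "\n")
        results["n_artifacts"] = len(self.manifest)
        results["manifest"] = str(p_manifest)
        return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns a summary dict incl. the manifest path."""
    return Pipeline(config).run()
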