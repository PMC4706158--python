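"""End-to-end pipeline: simulate/ingest -> QC -> preprocess -> decompose ->
dual regression -> synchrony -> statistics, with a machine-readable run
manifest (package versions, seed, config hash) stamped on every output."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, preprocess
from .decompose import GroupICA, detect_loading_outliers, select_components
from .dualreg import dual_regress
from .inference import cognition_regression, partial_correlation, rt_preprocess
from .simulate import SimulationConfig, simulate_cohort
from .synchrony import component_synchrony_table

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run.

    Either ``simulate`` is set (synthetic cohort) or ``run_paths`` +
    ``subject_table_path`` point at existing data. Analysis defaults:
    10 selected components, spike detector k = 5, exclusion rule k = 3 SD,
    100 s high-pass, 8 mm FWHM smoothing, 1000 bootstrap resamples,
    alpha = 0.05, age-group cut-offs 50/65 years.
    """

    out_dir: str = "cinesync_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    run_paths: list[str] = field(default_factory=list)
    subject_table_path: str | None = None
    parcellation_path: str | None = None
    events_path: str | None = None
    n_components: int | str = "auto"
    select_k: int = 10
    despike_k: float = 5.0
    exclusion_k: float = 3.0
    highpass_s: float = 100.0
    fwhm_mm: float = 8.0
    smooth: bool = True
    n_bootstrap: int = 1000
    alpha: float = 0.05
    age_cut_young: float = 50.0
    age_cut_old: float = 65.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        if payload.get("simulate") and "cognitive_effects" in payload["simulate"]:
            payload["simulate"]["cognitive_effects"] = {
                k: list(v) for k, v in payload["simulate"]["cognitive_effects"].items()
            }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(table: pd.DataFrame, cfg_hash: str) -> pd.DataFrame:
    table = table.copy()
    table["config_hash"] = cfg_hash
    return table


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order and write outputs under ``out_dir``.

    Reruns with identical config and seed produce byte-identical tables.
    Any stage failure aborts with the stage name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest: dict = {
        "package": "cinesync",
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "stages": [],
        "exclusions": [],
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            logger.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)
            return result

        return wrap

    # ingest / simulate -----------------------------------------------------
    def _ingest():
        if config.simulate is not None:
            sim = config.simulate
            runs, truth, table = simulate_cohort(sim)
            return runs, table
        if not config.run_paths or config.subject_table_path is None:
            raise ValueError("either 'simulate' or run_paths + subject table required")
        runs = [io.read_bold(p) for p in config.run_paths]
        table = io.read_subject_table(config.subject_table_path)
        return runs, table

    runs, subject_table = stage("ingest")(_ingest)
    manifest["n_subjects_in"] = len(runs)

    # qc --------------------------------------------------------------------
    def _qc():
        reports, masks = preprocess.qc_cohort(
            runs, threshold_k=config.despike_k, exclusion_k=config.exclusion_k
        )
        cleaned = [
            preprocess.despike(run, mask) for run, mask in zip(runs, masks)
        ]
        return reports, cleaned

    reports, runs_clean = stage("qc")(_qc)
    qc_table = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "spike_percentage": r.spike_percentage,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in reports
        ]
    )
    io.write_tsv(_stamp(qc_table, cfg_hash), out / "qc.tsv")
    kept = [i for i, r in enumerate(reports) if not r.excluded]
    for r in reports:
        if r.excluded:
            manifest["exclusions"].append(
                {"subject_id": r.subject_id, "reason": r.exclusion_reason}
            )
    runs_clean = [runs_clean[i] for i in kept]
    kept_ids = [r.subject_id for r in runs_clean]
    subject_table = subject_table[subject_table["subject_id"].isin(kept_ids)].reset_index(
        drop=True
    )

    # preprocess ------------------------------------------------------------
    def _preprocess():
        processed = []
        for run in runs_clean:
            if config.smooth:
                run = preprocess.smooth_gaussian(run, fwhm_mm=config.fwhm_mm)
            run = preprocess.grand_mean_scale(run)
            run = preprocess.highpass_filter(run, cutoff_s=config.highpass_s)
            processed.append(run)
        return processed

    runs_pp = stage("preprocess")(_preprocess)

    # decompose -------------------------------------------------------------
    def _decompose():
        cs = GroupICA(
            runs=runs_pp, n_components=config.n_components, seed=config.seed
        ).fit()
        k = min(config.select_k, cs.n_components)
        return select_components(cs, k=k)

    cs = stage("decompose")(_decompose)
    outliers = detect_loading_outliers(cs.loadings) if cs.n_subjects >= 3 else []
    for i in outliers:
        manifest["exclusions"].append(
            {"subject_id": cs.subject_ids[i], "reason": "loading_outlier"}
        )
    io.write_tsv(
        _stamp(
            pd.DataFrame(
                cs.loadings,
                columns=[f"comp_{i}" for i in range(cs.n_components)],
            ).assign(subject_id=cs.subject_ids),
            cfg_hash,
        ),
        out / "loadings.tsv",
    )
    io.write_tsv(
        _stamp(
            pd.DataFrame(
                cs.timecourses,
                columns=[f"comp_{i}" for i in range(cs.n_components)],
            ),
            cfg_hash,
        ),
        out / "group_timecourses.tsv",
    )
    if runs_pp:
        io.write_component_maps(
            cs.maps, runs_pp[0].grid_shape, runs_pp[0].affine, out / "group_maps.nii.gz"
        )

    # dual regression + synchrony ------------------------------------------
    def _synchrony():
        duals = [dual_regress(run, cs.maps) for run in runs_pp]
        return component_synchrony_table(
            [d.timecourses for d in duals],
            subject_maps=[d.maps for d in duals],
            group_maps=cs.maps,
            subject_ids=[r.subject_id for r in runs_pp],
        )

    sync_table = stage("synchrony")(_synchrony)
    io.write_tsv(_stamp(sync_table, cfg_hash), out / "synchrony.tsv")

    # statistics ------------------------------------------------------------
    def _stats():
        merged = sync_table.merge(subject_table, on="subject_id", validate="1:1")
        results = []
        edu = merged["education"].to_numpy(float)[:, None]
        age = merged["age"].to_numpy(float)
        for i in range(cs.n_components):
            pr = partial_correlation(age, merged[f"temporal_r_{i}"].to_numpy(), edu)
            results.append(
                {
                    "analysis": "age_vs_temporal_r",
                    "component": i,
                    "estimate": pr.estimate,
                    "t": pr.statistic,
                    "p": pr.p_value,
                }
            )
        pr = partial_correlation(age, merged["sync_score"].to_numpy(), edu)
        results.append(
            {
                "analysis": "age_vs_sync_score",
                "component": -1,
                "estimate": pr.estimate,
                "t": pr.statistic,
                "p": pr.p_value,
            }
        )
        stats_table = pd.DataFrame(results)

        # RT summaries + cognition regressions where columns are available
        if "rt_trials" in merged.columns:
            rt_rows = [
                rt_preprocess(tr) if tr is not None else (np.nan, np.nan, 0)
                for tr in merged["rt_trials"]
            ]
            merged["rt_mean"] = [r[0] for r in rt_rows]
            merged["rt_isd"] = [r[1] for r in rt_rows]
        reg_tables = []
        for score, covs in (
            ("fluid", ("education",)),
            ("crystallized", ("education",)),
            ("rt_isd", ("education", "rt_mean")),
            ("rt_mean", ("education", "rt_isd")),
        ):
            if score not in merged.columns:
                continue
            try:
                res = cognition_regression(merged, score, covariate_cols=covs)
            except ValueError as exc:
                logger.warning("skipping cognition model '%s': %s", score, exc)
                continue
            tab = res.coefficient_table().reset_index(names="predictor")
            tab.insert(0, "outcome", score)
            tab["model_r2"] = res.rsquared
            reg_tables.append(tab)
        return stats_table, reg_tables

    stats_table, reg_tables = stage("stats")(_stats)
    io.write_tsv(_stamp(stats_table, cfg_hash), out / "statistics.tsv")
    if reg_tables:
        io.write_tsv(
            _stamp(pd.concat(reg_tables, ignore_index=True), cfg_hash),
            out / "cognition_regressions.tsv",
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
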