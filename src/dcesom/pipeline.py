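"""End-to-end orchestration of the nine-stage analysis workflow.

Stages: simulate -> DeltaR1 relaxometry -> nested-model selection ->
dynamic radiomics maps -> NCER screening -> SOM training -> silhouette
cluster statistics -> nested cross-validation, with artifact writing and
provenance sidecars.  Every stage is deterministic given the configured
seeds.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .aif import AIFModel
from .cluster_stats import ModalityComparison, SilhouetteSweep, compare_modalities, threshold_sweep
from .ncv import NCVReport, run_ncv, split_folds
from .pk import ModelChoiceMap, map_pipeline, normalize_aif
from .protocol import AcquisitionProtocol, BaselineWindows
from .radiomics import compute_feature_maps, load_registry, normalize_series
from .relaxometry import ConcentrationSeries, estimate_concentration
from .screening import ModalityNCER, compute_ncer, screen_features
from .som import NodeProbabilityMaps, SOMConfig, SOMModel, probability_maps, train_ksom
from .synth import SimulatedStudy, post_t1_map, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run; YAML round-trippable."""

    # synthesis
    shape: tuple[int, int, int] = (64, 64, 3)
    n_acq: int = 400
    dt: float = 1.55
    injection_acq: int = 15
    hct: float = 0.45
    snr: float | None = 20.0
    kappa: float = 0.0
    seed: int = 0
    # relaxometry
    window_len: int = 10
    theta_policy: str = "pooled"
    # nested model selection
    alpha: float = 0.05
    # radiomics
    ng: int = 128
    conv_window: int = 5
    tail_len: int = 10
    exclude_first: int = 10
    dynamic_stride: int = 1  # temporal stride of the dynamic feature maps
    # screening
    ncer_threshold: float = 1.2
    features_per_echo: int = 13
    # SOM
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 200
    som_cover_steps: int = 100
    som_radius: float = 3.0
    # NCV
    k_folds: int = 10
    n_bootstrap: int = 1000
    max_profiles: int | None = None  # optional subsample for desk-scale runs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        for key in ("shape", "som_grid"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict()))
        return path

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(
            n_acq=self.n_acq, dt=self.dt, injection_acq=self.injection_acq, Hct=self.hct
        )

    def som_config(self, seed_offset: int = 0) -> SOMConfig:
        return SOMConfig(
            grid=self.som_grid,
            initial_radius=self.som_radius,
            max_epochs=self.som_epochs,
            cover_steps=self.som_cover_steps,
            seed=self.seed + 1000 + seed_offset,
        )


@dataclass
class RunResult:
    """In-memory artifacts of a full pipeline run."""

    config: RunConfig
    study: SimulatedStudy
    concentration: ConcentrationSeries
    model_map: ModelChoiceMap
    ncer_table: pd.DataFrame
    retained: dict[int, list[str]]  # echo -> modality ids (raw first)
    profiles: dict[str, np.ndarray]
    profile_labels: np.ndarray
    som_models: dict[str, SOMModel]
    som_probability_maps: dict[str, NodeProbabilityMaps]
    sweeps: dict[str, SilhouetteSweep]
    comparisons: dict[int, list[ModalityComparison]]
    ncv_report: NCVReport
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def n_modalities(self) -> int:
        return len(self.profiles)

    @property
    def profile_length(self) -> int:
        return next(iter(self.profiles.values())).shape[1]


def _modality_id(echo: int, feature: str | None) -> str:
    return f"echo{echo}" if feature is None else f"echo{echo}:{feature}"


def profile_timepoints(config: RunConfig) -> np.ndarray:
    """0-based acquisition indices entering dynamic profiles.

    The first ``exclude_first`` acquisitions (scanner-gain transient) are
    excluded; the rest may be strided for desk-scale runs.
    """
    return np.arange(config.exclude_first, config.n_acq, config.dynamic_stride)


def run_all(config: RunConfig, out_dir: Path | None = None) -> RunResult:
    """Execute every stage; optionally write artifacts under ``out_dir``."""
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %-12s %.2f s", stage, timings[stage])

    cfg_dict = config.to_dict()
    protocol = config.protocol()
    windows = BaselineWindows.default_for(protocol, length=config.window_len)

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    study = simulate_study(
        shape=config.shape,
        protocol=protocol,
        snr=config.snr,
        kappa=config.kappa,
        seed=config.seed,
    )
    t1post = post_t1_map(study.truth, study.delta_r1, protocol, windows)
    tick("simulate", t0)

    # --- relaxometry --------------------------------------------------------
    t0 = time.perf_counter()
    conc = estimate_concentration(
        study.series,
        study.truth.t1pre,
        t1post,
        mask=study.truth.brain_mask,
        windows=windows,
        theta_policy=config.theta_policy,
    )
    tick("dr1", t0)

    # --- nested model selection --------------------------------------------
    t0 = time.perf_counter()
    fit_mask = study.truth.brain_mask & conc.valid
    ref_mask = study.truth.reference_mask & fit_mask
    naif = normalize_aif(study.cp, conc.delta_r1[ref_mask], protocol.Hct)
    model_map = map_pipeline(
        conc.delta_r1, naif.cp, fit_mask, protocol.times, protocol.Hct, alpha=config.alpha
    )
    tick("nms", t0)

    # --- radiomics ----------------------------------------------------------
    t0 = time.perf_counter()
    norm1, norm2, norm_valid = normalize_series(
        study.series.echo1, study.series.echo2, study.truth.brain_mask, config.tail_len
    )
    echoes = {1: norm1, 2: norm2}
    registry = load_registry()
    all_ids = [spec.feature_id for spec in registry]

    base_tp = np.arange(windows.m - 1, windows.n)  # NCER baseline window
    plat_tp = np.arange(windows.o - 1, windows.p)  # NCER plateau window
    screen_tp = np.concatenate([base_tp, plat_tp])

    screen_stacks = {
        echo: compute_feature_maps(
            echoes[echo],
            norm_valid,
            all_ids,
            ng=config.ng,
            window=config.conv_window,
            timepoints=screen_tp,
        )
        for echo in (1, 2)
    }
    tick("radiomics-screen", t0)

    # --- screening ----------------------------------------------------------
    t0 = time.perf_counter()
    n_base = base_tp.size
    base_pos = np.arange(n_base)
    plat_pos = np.arange(n_base, screen_tp.size)
    ncer_rows = []
    retained: dict[int, list[str]] = {}
    for echo in (1, 2):
        stack = screen_stacks[echo]
        region_valid = stack.valid & (model_map.labels > 0)
        entries = []
        raw_id = _modality_id(echo, None)
        raw_val = compute_ncer(
            echoes[echo][..., screen_tp], model_map.labels, region_valid, base_pos, plat_pos
        )
        entries.append(ModalityNCER(raw_id, [raw_val], evaluable=np.isfinite(raw_val)))
        for fid in all_ids:
            val = compute_ncer(
                stack.maps[fid], model_map.labels, region_valid, base_pos, plat_pos
            )
            entries.append(
                ModalityNCER(_modality_id(echo, fid), [val], evaluable=np.isfinite(val))
            )
        retained[echo] = screen_features(
            entries,
            threshold=config.ncer_threshold,
            always_keep=(raw_id,),
            top_k=config.features_per_echo,
        )
        for e in entries:
            ncer_rows.append(
                {
                    "modality": e.modality_id,
                    "echo": echo,
                    "mean_ncer": e.mean_ncer,
                    "retained": e.modality_id in retained[echo],
                }
            )
    ncer_table = pd.DataFrame(ncer_rows)
    tick("screen", t0)

    # --- dynamic maps for retained features + profile assembly --------------
    t0 = time.perf_counter()
    prof_tp = profile_timepoints(config)
    dyn_stacks = {}
    for echo in (1, 2):
        feat_ids = [m.split(":", 1)[1] for m in retained[echo] if ":" in m]
        if feat_ids:
            dyn_stacks[echo] = compute_feature_maps(
                echoes[echo],
                norm_valid,
                feat_ids,
                ng=config.ng,
                window=config.conv_window,
                timepoints=prof_tp,
            )
    tick("radiomics-dyn", t0)

    t0 = time.perf_counter()
    voxel_ok = fit_mask & norm_valid & (model_map.labels > 0)
    for echo in dyn_stacks:
        voxel_ok &= dyn_stacks[echo].valid
    labels_flat = model_map.labels[voxel_ok]
    profiles: dict[str, np.ndarray] = {}
    for echo in (1, 2):
        for mid in retained[echo]:
            if ":" in mid:
                fid = mid.split(":", 1)[1]
                profiles[mid] = dyn_stacks[echo].maps[fid][voxel_ok]
            else:
                profiles[mid] = echoes[echo][voxel_ok][:, prof_tp]
    if config.max_profiles is not None and labels_flat.size > config.max_profiles:
        rng = np.random.default_rng(config.seed + 77)
        pick = np.sort(rng.choice(labels_flat.size, config.max_profiles, replace=False))
        labels_flat = labels_flat[pick]
        profiles = {k: v[pick] for k, v in profiles.items()}

    # --- SOM + cluster statistics -------------------------------------------
    som_models: dict[str, SOMModel] = {}
    som_pmaps: dict[str, NodeProbabilityMaps] = {}
    sweeps: dict[str, SilhouetteSweep] = {}
    for mid, prof in profiles.items():
        model = train_ksom(prof, config.som_config())
        pmap = probability_maps(model, prof, labels_flat)
        som_models[mid] = model
        som_pmaps[mid] = pmap
        sweeps[mid] = threshold_sweep(model, pmap, modality_id=mid)
    comparisons = {
        echo: compare_modalities(
            sweeps[_modality_id(echo, None)],
            [sweeps[mid] for mid in retained[echo] if ":" in mid],
        )
        for echo in (1, 2)
    }
    tick("som+stats", t0)

    # --- NCV -----------------------------------------------------------------
    t0 = time.perf_counter()
    plan = split_folds(labels_flat.size, k=config.k_folds, seed=config.seed + 5)
    ncv_report = run_ncv(
        profiles,
        labels_flat,
        plan,
        som_config=config.som_config(seed_offset=500),
        n_bootstrap=config.n_bootstrap,
        seed=config.seed + 9,
    )
    tick("ncv", t0)

    result = RunResult(
        config=config,
        study=study,
        concentration=conc,
        model_map=model_map,
        ncer_table=ncer_table,
        retained=retained,
        profiles=profiles,
        profile_labels=labels_flat,
        som_models=som_models,
        som_probability_maps=som_pmaps,
        sweeps=sweeps,
        comparisons=comparisons,
        ncv_report=ncv_report,
        timings=timings,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir), cfg_dict)
    return result


def write_artifacts(result: RunResult, out_dir: Path, cfg_dict: dict) -> None:
    """Write the run's tabular and volumetric artifacts with provenance."""
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = result.config.seed
    dio.write_json(out_dir / "config.json", cfg_dict)
    dio.write_nifti(out_dir / "labels.nii.gz", result.model_map.labels.astype(np.int16))
    for name in ("vp", "ktrans", "kep", "ve"):
        dio.write_nifti(out_dir / f"{name}.nii.gz", getattr(result.model_map, name))
    dio.write_nifti(out_dir / "theta_est.nii.gz", result.concentration.theta_est)
    result.ncer_table.to_csv(out_dir / "ncer.csv", index=False)

    sweep_rows = []
    for mid, sweep in result.sweeps.items():
        for i, tau in enumerate(sweep.thresholds):
            sweep_rows.append(
                {
                    "modality": mid,
                    "threshold": tau,
                    "mean_sc": sweep.mean_sc[i],
                    "sd_sc": sweep.sd_sc[i],
                    "n_nodes": sweep.n_nodes[i],
                }
            )
    pd.DataFrame(sweep_rows).to_csv(out_dir / "silhouette_sweeps.csv", index=False)

    comp_rows = []
    for echo, comps in result.comparisons.items():
        for c in comps:
            comp_rows.append(
                {
                    "echo": echo,
                    "modality": c.modality_id,
                    "dsc_percent": c.dsc_percent,
                    "levene_p": c.levene_p,
                    "omnibus_test": c.omnibus_test,
                    "omnibus_p": c.omnibus_p,
                    "adjusted_p": c.adjusted_p,
                    "significant": c.significant,
                }
            )
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)

    ncv_rows = []
    for r in result.ncv_report.results:
        ncv_rows.append(
            {
                "modality": r.modality_id,
                "auc": r.auc.value,
                "auc_lo": r.auc.lower,
                "auc_hi": r.auc.upper,
                "balanced_accuracy": r.balanced_accuracy.value,
                "ba_lo": r.balanced_accuracy.lower,
                "ba_hi": r.balanced_accuracy.upper,
                "f1": r.f1.value,
                "f1_lo": r.f1.lower,
                "f1_hi": r.f1.upper,
                "models_trained": r.n_models_trained,
            }
        )
    pd.DataFrame(ncv_rows).to_csv(out_dir / "ncv.csv", index=False)
    dio.write_provenance(out_dir / "provenance.json", cfg_dict, seed, "run-all")
    dio.write_json(out_dir / "timings.json", result.timings)
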