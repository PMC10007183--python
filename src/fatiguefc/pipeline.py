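"""End-to-end orchestration: simulate/load -> preprocess -> localize ->
parcellate -> features -> classify -> contrast.

A :class:`PipelineConfig` fully determines a run; a single master seed is
expanded into per-stage seeds through a seed sequence so that exact reruns
are bit-identical.  ``run_pipeline`` executes one feature space and band
set; ``compare_feature_spaces`` runs the classifier identically over the
three feature extractors (source-space connectivity, sensor-space
connectivity, relative band power) for the comparison table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandDefinition, get_band
from .classify import (
    ClassificationResults,
    ContrastReport,
    FatigueClassifier,
    LabeledFeatures,
    condition_contrast,
    rfe_select,
)
from .connectivity import (
    connectivity_matrix,
    lower_triangle,
    psd_features,
)
from .headmodel import (
    HeadModelParams,
    build_sensor_array,
    build_source_space,
    compute_leadfield,
    load_leadfield,
)
from .inverse import apply_inverse, compute_inverse_operator
from .io import checksum, features_to_frame, read_dataset_manifest
from .parcellation import build_synthetic_atlas, sign_flip_average
from .preprocess import bandpass, bss_cca_denoise, resample
from .recording import Recording
from .simulate import CouplingSpec, SimulationConfig, generate_dataset

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "compare_feature_spaces"]

FEATURE_SPACES = ("source-fc", "sensor-fc", "psd")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run.

    Exactly one input source: either ``data_manifest`` (a dataset on disk)
    or ``simulation`` (synthetic study conditions).
    """

    # input
    data_manifest: "str | None" = None
    simulation: "SimulationConfig | None" = None
    # head model / source space
    head_params: HeadModelParams = field(default_factory=HeadModelParams)
    n_vertices_per_hemisphere: int = 64
    n_rois_per_hemisphere: int = 8
    leadfield_path: "str | None" = None
    # preprocessing
    target_fs: "float | None" = None
    denoise: bool = False
    cca_threshold: float = 0.6
    # inverse
    inverse_lambda: "float | None" = None
    # features
    feature_space: str = "source-fc"
    bands: list = field(default_factory=lambda: ["beta"])
    prefilter: bool = False  # band-pass ROI/sensor series before PLI
    # classification
    rfe_keep_fraction: "float | None" = 0.13
    rfe_step_fraction: float = 0.05
    grid: "list | str | None" = None
    svm_params: "dict | None" = None
    cv_repetitions: int = 50
    n_permutations: int = 0  # 0 disables the permutation test
    permutation_fast_mode: bool = True
    subject_level_folds: bool = True
    # misc
    seed: int = 0
    out_dir: "str | None" = None

    def __post_init__(self) -> None:
        if (self.data_manifest is None) == (self.simulation is None):
            raise ValueError(
                "exactly one input source required: data_manifest or simulation"
            )
        if self.feature_space not in FEATURE_SPACES:
            raise ValueError(
                f"feature_space must be one of {FEATURE_SPACES}, "
                f"got {self.feature_space!r}"
            )
        self.bands = [get_band(b) for b in self.bands]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            for key in ("couplings_alert", "couplings_fatigue"):
                sim[key] = [CouplingSpec(**c) for c in sim.get(key, [])]
            raw["simulation"] = SimulationConfig(**sim)
        if "head_params" in raw and raw["head_params"] is not None:
            hp = raw["head_params"]
            for k in ("radii", "conductivities"):
                if k in hp:
                    hp[k] = tuple(hp[k])
            raw["head_params"] = HeadModelParams(**hp)
        return cls(**raw)


@dataclass
class RunManifest:
    """Provenance record of a pipeline run."""

    config: dict
    derived_seeds: dict
    stage_log: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def log(self, stage: str, t0: float, **info) -> None:
        self.stage_log.append(
            {"stage": stage, "seconds": round(time.time() - t0, 3), **info}
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "derived_seeds": self.derived_seeds,
             "stage_log": self.stage_log, "checksums": self.checksums},
            indent=2, default=str))


def _derive_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ("simulation", "atlas", "source_space", "cv", "permutation")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _build_geometry(config: PipelineConfig, seeds: dict):
    sensors = build_sensor_array("standard_32", config.head_params.radii[2])
    sources = build_source_space(
        config.n_vertices_per_hemisphere,
        seed=seeds["source_space"],
        inner_skull_radius=config.head_params.radii[0],
    )
    if config.leadfield_path:
        lf = load_leadfield(config.leadfield_path, sensors.n_sensors,
                            sources.n_dipoles)
    else:
        lf = compute_leadfield(sensors, sources, config.head_params)
    atlas = build_synthetic_atlas(sources, config.n_rois_per_hemisphere,
                                  seed=seeds["atlas"])
    return sensors, sources, lf, atlas


def _get_recordings(config: PipelineConfig, seeds: dict, geometry) -> list[Recording]:
    sensors, sources, lf, atlas = geometry
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != seeds["simulation"]:
            from dataclasses import replace

            sim = replace(sim, seed=seeds["simulation"])
        return generate_dataset(sim, atlas, sources, lf).recordings
    return read_dataset_manifest(config.data_manifest)


def _preprocess(rec: Recording, config: PipelineConfig) -> Recording:
    if config.target_fs is not None and config.target_fs < rec.fs:
        rec = resample(rec, config.target_fs)
    if config.denoise:
        rec = bss_cca_denoise(rec, config.cca_threshold)
    return rec


def extract_features(
    recordings: list[Recording],
    space: str,
    band: BandDefinition,
    geometry=None,
    inverse_op=None,
    prefilter: bool = False,
) -> LabeledFeatures:
    """Per-recording feature vectors for one band in one feature space."""
    from .parcellation import ROITimeSeries

    vectors, cms = [], []
    for rec in recordings:
        if space == "psd":
            fv = psd_features(rec, [band])
        else:
            if space == "source-fc":
                sensors, sources, lf, atlas = geometry
                est = apply_inverse(inverse_op, rec, sources)
                series = sign_flip_average(est, atlas, sources)
                if prefilter:
                    filtered = bandpass(
                        Recording(series.data, series.fs), band)
                    series = ROITimeSeries(filtered.data, series.roi_names,
                                           series.fs)
            else:
                series = bandpass(rec, band) if prefilter else rec
            cm = connectivity_matrix(series, band,
                                     space="source" if space == "source-fc"
                                     else "sensor")
            cms.append(cm)
            fv = lower_triangle(cm)
        vectors.append(fv)
    df = features_to_frame(vectors,
                           [r.subject_id for r in recordings],
                           [r.condition for r in recordings])
    feats = LabeledFeatures.from_dataframe(df)
    feats.connectivity_matrices = cms  # kept for the contrast stage
    return feats


def run_pipeline(config: PipelineConfig):
    """Execute the configured analysis end to end.

    Returns
    -------
    manifest : RunManifest
    results : dict band-name -> ClassificationResults (with .permutation)
    contrasts : dict band-name -> ContrastReport (connectivity spaces only)
    """
    seeds = _derive_seeds(config.seed)
    manifest = RunManifest(config=_config_dict(config), derived_seeds=seeds)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    geometry = _build_geometry(config, seeds)
    manifest.checksums["leadfield"] = checksum(geometry[2].gain)
    manifest.log("geometry", t0, n_vertices=geometry[1].n_vertices,
                 n_rois=geometry[3].n_rois)

    t0 = time.time()
    recordings = _get_recordings(config, seeds, geometry)
    recordings = [_preprocess(r, config) for r in recordings]
    manifest.log("data", t0, n_recordings=len(recordings))

    inverse_op = None
    if config.feature_space == "source-fc":
        t0 = time.time()
        inverse_op = compute_inverse_operator(geometry[2],
                                              lam=config.inverse_lambda)
        manifest.log("inverse_operator", t0, lam=inverse_op.lam)

    results: dict = {}
    contrasts: dict = {}
    for band in config.bands:
        t0 = time.time()
        feats = extract_features(recordings, config.feature_space, band,
                                 geometry, inverse_op, config.prefilter)
        manifest.checksums[f"features_{band.name}"] = checksum(feats.X)
        manifest.log(f"features_{band.name}", t0, n_features=feats.n_features)
        if out:
            frame = pd.DataFrame(feats.X, columns=feats.feature_labels)
            frame.insert(0, "subject_id", feats.subject_ids)
            frame.insert(1, "condition",
                         np.where(feats.y == 1, "fatigue", "alert"))
            frame.to_csv(out / f"features_{band.name}.tsv", sep="\t", index=False)

        t0 = time.time()
        model = FatigueClassifier(
            feats,
            rfe_keep_fraction=config.rfe_keep_fraction,
            rfe_step_fraction=config.rfe_step_fraction,
            grid=config.grid, svm_params=config.svm_params,
            subject_level=config.subject_level_folds,
        )
        res = model.fit(n_reps=config.cv_repetitions, seed=seeds["cv"])
        if config.n_permutations > 0:
            res.permutation = model.permutation_test(
                n_perm=config.n_permutations, seed=seeds["permutation"],
                fast_mode=config.permutation_fast_mode,
            )
        results[band.name] = res
        manifest.log(f"classify_{band.name}", t0,
                     accuracy=round(res.accuracy_mean, 4))

        if config.feature_space != "psd":
            cms = feats.connectivity_matrices
            alert_ms = [cm for cm, r in zip(cms, recordings)
                        if r.condition == "alert"]
            fatigue_ms = [cm for cm, r in zip(cms, recordings)
                          if r.condition == "fatigue"]
            keep = config.rfe_keep_fraction or 1.0
            sel, _ = rfe_select(feats, keep_fraction=keep,
                                step_fraction=config.rfe_step_fraction) \
                if keep < 1.0 else (np.arange(feats.n_features), None)
            atlas = geometry[3] if config.feature_space == "source-fc" else None
            contrasts[band.name] = condition_contrast(
                alert_ms, fatigue_ms, list(sel), atlas)
            if out:
                contrasts[band.name].to_dataframe().to_csv(
                    out / f"contrast_{band.name}.tsv", sep="\t", index=False)

    if out:
        manifest.write(out / "manifest.json")
        report = {
            band: {
                "accuracy": res.accuracy_mean,
                "sensitivity": res.sensitivity_mean,
                "specificity": res.specificity_mean,
                "p_value": getattr(res, "permutation", None).p_value
                if getattr(res, "permutation", None) else None,
            }
            for band, res in results.items()
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return manifest, results, contrasts


def compare_feature_spaces(config: PipelineConfig) -> pd.DataFrame:
    """Accuracy of the three feature extractors across the band list.

    The classifier settings, folds and seeds are identical across spaces;
    only the feature extraction differs.  Returns a spaces x bands table.
    """
    seeds = _derive_seeds(config.seed)
    geometry = _build_geometry(config, seeds)
    recordings = [_preprocess(r, config)
                  for r in _get_recordings(config, seeds, geometry)]
    inverse_op = compute_inverse_operator(geometry[2], lam=config.inverse_lambda)

    table = pd.DataFrame(index=list(FEATURE_SPACES),
                         columns=[b.name for b in config.bands], dtype=float)
    for band in config.bands:
        for space in FEATURE_SPACES:
            feats = extract_features(recordings, space, band, geometry,
                                     inverse_op, config.prefilter)
            model = FatigueClassifier(
                feats, rfe_keep_fraction=config.rfe_keep_fraction,
                rfe_step_fraction=config.rfe_step_fraction,
                grid=config.grid, svm_params=config.svm_params,
                subject_level=config.subject_level_folds,
            )
            res = model.fit(n_reps=config.cv_repetitions, seed=seeds["cv"])
            table.loc[space, band.name] = res.accuracy_mean
    return table


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["bands"] = [b.name for b in config.bands]
    return d
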