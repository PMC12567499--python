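"""End-to-end orchestration: simulate/load -> filter -> ICA -> localize ->
feature extraction -> train/test split + cross-validation -> BP training ->
evaluation.  Fully deterministic given the configured seed."""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as mio
from .bp import ForceRegressor, TrainHistory
from .config import RunConfig
from .evaluation import EvalReport, evaluate_predictions, kfold, split_train_test
from .grid import ElectrodeGrid
from .ica import IcaResult, separate
from .localization import (
    ComponentLabel,
    MtuLocation,
    classify_components,
    localize_sources,
    match_locations,
)
from .preprocessing import (
    SemgRecording,
    mvc_normalize,
    preprocess_recording,
    rms_envelope,
    sliding_windows,
    window_mean,
)
from .synthetic import simulate_posture_recording


@dataclass
class PostureResult:
    posture: str
    recording: SemgRecording
    ica: IcaResult
    labels: list[ComponentLabel]
    locations: list[MtuLocation]
    localization_errors_mm: Optional[list[float]]
    features: np.ndarray     # (n_windows, n_emg_components)
    targets: np.ndarray      # (n_windows,) window-mean force


@dataclass
class PipelineResult:
    postures: list[PostureResult]
    regressor: ForceRegressor
    history: TrainHistory
    report: EvalReport
    cv_reports: list[EvalReport]
    test_actual: np.ndarray
    test_predicted: np.ndarray
    log: list[dict] = field(default_factory=list)


def _extract_features(
    recording: SemgRecording,
    ica_result: IcaResult,
    labels: list[ComponentLabel],
    config: RunConfig,
    mvc_references: Optional[list[np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed RMS of EMG-labelled sources (MVC-normalized) + mean force."""
    windows = sliding_windows(
        recording.n_samples,
        recording.fs_hz,
        config.preprocess.window_s,
        config.preprocess.step_s,
    )
    emg_idx = [lab.index for lab in labels if lab.label == "emg_source"]
    if not emg_idx:
        raise RuntimeError("no components classified as EMG sources")
    feats = []
    for i in emg_idx:
        src = ica_result.sources[i]
        trials = mvc_references if mvc_references else [src]
        feats.append(rms_envelope(mvc_normalize(src, trials), windows))
    X = np.stack(feats, axis=1)
    y = (
        window_mean(recording.force, windows)
        if recording.force is not None
        else np.zeros(len(windows))
    )
    return X, y


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full localization + force-prediction pipeline.

    With no recording paths in the config, the synthetic generator produces
    one recording per configured posture.  Returns the result bundle and,
    when ``out_dir`` is given, writes locations, evaluation report, model
    and a structured stage log as JSON.
    """
    log: list[dict] = []

    def _stage(name: str, t0: float, **extra) -> None:
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4), **extra})

    grid = ElectrodeGrid(config.grid.rows, config.grid.cols, config.grid.pitch_mm)
    recordings: list[tuple[SemgRecording, Optional[list[tuple[float, float]]]]] = []

    t0 = time.perf_counter()
    if config.recording_csv is not None:
        rec = mio.read_recording(config.recording_csv, config.recording_sidecar)
        recordings.append((rec, None))
    else:
        sim = config.simulator
        for p_i, posture in enumerate(sim.postures):
            rec, truth = simulate_posture_recording(
                posture,
                grid,
                n_sources=sim.n_sources,
                fs_hz=config.fs_hz,
                cycles=sim.cycles,
                cycle_s=sim.cycle_s,
                rest_s=sim.rest_s,
                snr_db=sim.snr_db,
                powerline=(sim.powerline_hz, sim.powerline_amplitude),
                source_spread_mm=sim.source_spread_mm,
                force_gain_n=sim.force_gain_n,
                force_noise_sd_n=sim.force_noise_sd_n,
                dominance_gain=sim.dominance_gain,
                seed=config.seed + 10 * p_i,
            )
            recordings.append((rec, truth.source_locations_mm))
    _stage("acquire", t0, n_recordings=len(recordings))

    posture_results: list[PostureResult] = []
    all_X, all_y = [], []
    for rec, truth_locations in recordings:
        t0 = time.perf_counter()
        filtered = preprocess_recording(rec, config.preprocess.to_dataclass())
        _stage("preprocess", t0, posture=rec.posture)

        t0 = time.perf_counter()
        ica_res = separate(filtered, config.ica.to_dataclass(seed=config.seed))
        _stage("separate", t0, posture=rec.posture, n_iter=ica_res.n_iter,
               converged=ica_res.converged)

        t0 = time.perf_counter()
        loc_cfg = config.localization
        labels = classify_components(
            ica_res.sources,
            rec.fs_hz,
            band_hz=(loc_cfg.emg_band_low_hz, loc_cfg.emg_band_high_hz),
            threshold=loc_cfg.threshold,
            powerline_hz=loc_cfg.powerline_hz,
            notch_halfwidth_hz=loc_cfg.notch_halfwidth_hz,
        )
        locations = localize_sources(ica_res.mixing_estimate, grid, labels)
        errors = (
            match_locations(locations, truth_locations)
            if truth_locations and locations
            else None
        )
        _stage("localize", t0, posture=rec.posture,
               n_emg_components=len(locations))

        X, y = _extract_features(filtered, ica_res, labels, config)
        posture_results.append(
            PostureResult(
                posture=rec.posture or "?",
                recording=rec,
                ica=ica_res,
                labels=labels,
                locations=locations,
                localization_errors_mm=errors,
                features=X,
                targets=y,
            )
        )
        all_X.append(X)
        all_y.append(y)

    # postures may expose different numbers of EMG components; pad feature
    # matrices to a common width with zeros so windows remain comparable
    width = max(X.shape[1] for X in all_X)
    all_X = [
        np.pad(X, ((0, 0), (0, width - X.shape[1]))) if X.shape[1] < width else X
        for X in all_X
    ]
    X = np.vstack(all_X)
    y = np.concatenate(all_y)

    t0 = time.perf_counter()
    ev = config.evaluation
    train_idx, test_idx = split_train_test(
        len(y), (ev.train_ratio, ev.test_ratio), seed=config.seed
    )
    active_thr = ev.active_threshold_fraction * float(y.max())

    cv_reports: list[EvalReport] = []
    for fit_idx, val_idx in kfold(train_idx, ev.cv_folds, seed=config.seed):
        reg = ForceRegressor(
            config.train.to_dataclass(seed=config.seed),
            hidden_layers=config.train.hidden_layers,
        ).fit(X[fit_idx], y[fit_idx])
        pred = reg.predict(X[val_idx])
        if np.any(y[val_idx] > active_thr):
            cv_reports.append(
                evaluate_predictions(y[val_idx], pred, active_threshold=active_thr)
            )
    _stage("cross_validate", t0, folds=len(cv_reports))

    t0 = time.perf_counter()
    regressor = ForceRegressor(
        config.train.to_dataclass(seed=config.seed),
        hidden_layers=config.train.hidden_layers,
    ).fit(X[train_idx], y[train_idx])
    _stage("train", t0, epochs=regressor.history.n_epochs,
           stop_reason=regressor.history.stop_reason)

    t0 = time.perf_counter()
    test_pred = regressor.predict(X[test_idx])
    cls_thr = ev.classification_threshold_pct_mvc
    report = evaluate_predictions(
        y[test_idx],
        test_pred,
        active_threshold=active_thr,
        classification_threshold=(
            cls_thr / 100.0 * float(y.max()) if cls_thr is not None else None
        ),
    )
    _stage("evaluate", t0, n_test=len(test_idx))

    result = PipelineResult(
        postures=posture_results,
        regressor=regressor,
        history=regressor.history,
        report=report,
        cv_reports=cv_reports,
        test_actual=y[test_idx],
        test_predicted=test_pred,
        log=log,
    )
    if out_dir is not None:
        _write_artifacts(result, config, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    locations_doc = {
        pr.posture: [
            {
                "component": loc.component,
                "centroid_mm": list(loc.centroid_mm),
                "peak_electrode": list(loc.peak_electrode),
                "confidence": loc.confidence,
                **(
                    {}
                    if pr.localization_errors_mm is None
                    else {"matched_errors_mm": pr.localization_errors_mm}
                ),
            }
            for loc in pr.locations
        ]
        for pr in result.postures
    }
    mio.write_json(locations_doc, out_dir / "locations.json")
    mio.write_json(result.report.to_dict(), out_dir / "eval_report.json")
    mio.write_json(
        {
            "cv_reports": [r.to_dict() for r in result.cv_reports],
            "train_epochs": result.history.n_epochs,
            "stop_reason": result.history.stop_reason,
        },
        out_dir / "cv_report.json",
    )
    if result.regressor.params is not None:
        mio.save_model(result.regressor.params, out_dir / "model.json")
    mio.write_json({"seed": config.seed, "stages": result.log}, out_dir / "run_log.json")
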