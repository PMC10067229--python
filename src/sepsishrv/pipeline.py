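"""Configuration, file I/O and the one-command end-to-end run.

Conventions: all times are seconds from ED admission inside the pipeline;
ECG is read/written as two-column delimited time/voltage text with a small
``#``-prefixed header (sampling rate, admission offset, patient id); every
stage table is plain delimited text with explicit column headers; missing
values serialize as empty fields. Each output carries the configuration hash
and root seed so reruns are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, model, preprocessing, stratification, synthetic
from .features import FEATURE_NAMES, SpectralBands, feature_vector
from .preprocessing import ECGRecord, NNSeries, PanTompkinsParams

__all__ = ["PipelineConfig", "read_ecg", "write_ecg", "process_record", "run_pipeline"]

logger = logging.getLogger("sepsishrv")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study defaults."""

    window_length_s: float = 300.0
    quality_threshold_beats: int = 60  # 20% of the 300 expected beats / 5 min
    bin_length_s: float = 3 * 3600.0
    adarri_k_iqr: float = 4.0
    adarri_min_threshold_ms: float = 100.0
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    spectral_method: str = "lombscargle"
    screening_alpha: float = 0.05
    candidate_gate: float = 0.20
    model_features: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    from_ecg: bool = False  # True: render + detect R-peaks; False: start from tachograms
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # overrides for SimulationConfig
    detector: dict = field(default_factory=dict)  # overrides for PanTompkinsParams

    def __post_init__(self) -> None:
        if not 0.0 < self.candidate_gate < 1.0:
            raise ValueError("candidate gate must lie in (0, 1)")
        for name in ("window_length_s", "quality_threshold_beats", "bin_length_s",
                     "screening_alpha", "sampen_r_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def simulation_config(self) -> synthetic.SimulationConfig:
        return synthetic.SimulationConfig(seed=self.seed, **self.simulation)


# -- ECG text I/O ------------------------------------------------------------


def write_ecg(record: ECGRecord, path: str | Path) -> None:
    """Two-column time/voltage text with a #-header."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {record.sampling_rate}\n")
        fh.write(f"# t0_s: {record.t0}\n")
        fh.write(f"# patient_id: {record.patient_id or ''}\n")
        fh.write("time_s\tvoltage_mv\n")
        np.savetxt(fh, np.column_stack([record.times, record.samples]), fmt="%.6f\t%.6f")


def read_ecg(path: str | Path) -> ECGRecord:
    """Read a delimited time/voltage record written by :func:`write_ecg`.

    The sampling rate comes from the header; the time column is validated for
    monotonicity and non-numeric rows are reported by line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
            else:
                break
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", engine="python")
        times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy()
        volts = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy()
    except (ValueError, TypeError) as exc:
        # locate the first offending row for a precise message
        raw = pd.read_csv(path, sep=r"\s+", comment="#", engine="python", dtype=str)
        for i, (a, b) in enumerate(zip(raw.iloc[:, 0], raw.iloc[:, 1])):
            try:
                float(a), float(b)
            except (TypeError, ValueError):
                raise ValueError(f"{path.name}: non-numeric value in data row {i + 1}") from exc
        raise
    if len(times) > 1:
        dt = np.diff(times)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2
            raise ValueError(f"{path.name}: time column not strictly increasing at row {bad}")
    fs = float(meta.get("sampling_rate_hz", 0)) or (
        1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    )
    if fs <= 0:
        raise ValueError(f"{path.name}: cannot determine sampling rate")
    t0 = float(meta.get("t0_s", times[0] if len(times) else 0.0))
    return ECGRecord(volts, sampling_rate=fs, t0=t0, patient_id=meta.get("patient_id") or None)


def write_nn(nn: NNSeries, path: str | Path) -> None:
    nn.to_frame().to_csv(path, sep="\t", index=False)


def read_nn(path: str | Path, patient_id: str | None = None) -> NNSeries:
    df = pd.read_csv(path, sep="\t")
    return NNSeries(
        df["nn_ms"].to_numpy(), df["end_time_s"].to_numpy(),
        df["artifact"].to_numpy(bool), patient_id,
    )


# -- per-patient processing --------------------------------------------------


def process_record(
    source: ECGRecord | NNSeries,
    record_duration: float,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Raw ECG (or tachogram) → artifact-corrected windows → feature rows.

    Returns one row per *retained* 5-minute window with the 17 features,
    window bookkeeping and quality flags.
    """
    if isinstance(source, ECGRecord):
        peaks = preprocessing.detect_r_peaks(source, PanTompkinsParams(**config.detector))
        nn = preprocessing.compute_nn_intervals(peaks)
        pid = source.patient_id
    else:
        nn = source
        pid = source.patient_id
    if len(nn) == 0:
        return pd.DataFrame()
    clean = preprocessing.correct_artifacts(
        nn, k_iqr=config.adarri_k_iqr, min_threshold_ms=config.adarri_min_threshold_ms
    )
    windows = preprocessing.segment_windows(clean, record_duration)
    rows = []
    for w in windows:
        if not w.retained:
            continue
        vec = feature_vector(
            w,
            bands=SpectralBands(),
            sampen_m=config.sampen_m,
            sampen_r_factor=config.sampen_r_factor,
            spectral_method=config.spectral_method,
        )
        vec["patient_id"] = pid
        vec["n_beats"] = w.n_beats
        rows.append(vec)
    return pd.DataFrame(rows)


# -- end-to-end run ----------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """simulate → preprocess → features → aggregate → stratify → analyze.

    Writes every stage table, a run log and a JSON summary report to
    ``outdir`` and returns the report. Stage failures halt with the stage
    name and offending patient id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    chash = config.config_hash()
    logger.info("config hash %s seed %d", chash, config.seed)

    sim = config.simulation_config()
    cohort = synthetic.simulate_cohort(sim, render=config.from_ecg)
    cohort.ground_truth_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)

    feature_frames = []
    for p in cohort.patients:
        try:
            source = p.ecg if (config.from_ecg and p.ecg is not None) else p.nn
            feats = process_record(source, min(sim.record_duration, p.dropout_time_h * 3600.0), config)
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess patient={p.patient_id}: {exc}") from exc
        if len(feats):
            feature_frames.append(feats)
    features_df = pd.concat(feature_frames, ignore_index=True)
    features_df.insert(0, "config_hash", chash)
    features_df.to_csv(outdir / "features.tsv", sep="\t", index=False)

    summaries = aggregation.aggregate_features(features_df, config.model_features, config.bin_length_s)
    summaries.insert(0, "config_hash", chash)
    summaries.to_csv(outdir / "summaries_3h.tsv", sep="\t", index=False)

    labels = stratification.classify_cohort([p.course for p in cohort.patients])
    labels.insert(0, "config_hash", chash)
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    kw = model.kruskal_wallis_screen(
        summaries, labels, config.model_features, kinds=("mean", "slope"),
        alpha=config.screening_alpha,
    )
    kw.to_csv(outdir / "kruskal_wallis.tsv", sep="\t", index=False)

    design, excluded = aggregation.first_interval_matrix(summaries, config.model_features)
    design.columns = [c.removeprefix("mean_") for c in design.columns]
    lab_map = labels.set_index("patient_id")["label"]
    y = (lab_map.loc[design.index] == "POD").astype(int)
    design.to_csv(outdir / "design_bin0.tsv", sep="\t")
    det = model.DeteriorationModel(design, y, candidate_gate=config.candidate_gate).fit()
    det.univariate.to_csv(outdir / "univariate_logistic.tsv", sep="\t", index=False)
    if det.selected:
        det.odds_ratios.to_csv(outdir / "multivariate_odds_ratios.tsv", sep="\t")
    (outdir / "model_summary.txt").write_text(det.summary() + "\n")

    # comparator scores on the modelled patients
    courses = {p.patient_id: p.course for p in cohort.patients}
    qsofa = np.array(
        [model.qsofa_score(courses[p].respiratory_rate, courses[p].systolic_bp, courses[p].gcs)
         for p in design.index]
    )
    severity = np.array([courses[p].sepsis_severity for p in design.index])
    hrv_pred = det.predict()
    yv = y.to_numpy()
    roc_rows = []
    for name, score in [("HRV", hrv_pred), ("qSOFA", qsofa), ("SepsisSeverity", severity)]:
        roc_rows.append({"score": name, "auroc": model.roc_auc(score, yv)})
    roc_df = pd.DataFrame(roc_rows)
    cmp_q = model.delong_compare(hrv_pred, qsofa, yv)
    cmp_s = model.delong_compare(hrv_pred, severity, yv)
    roc_df.to_csv(outdir / "roc_auc.tsv", sep="\t", index=False)

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_patients": len(cohort),
        "n_modelled": len(design),
        "excluded_no_bin0": excluded,
        "group_counts": labels["label"].value_counts().to_dict(),
        "selected_features": det.selected,
        "diagnostics": det.diagnostics(),
        "auroc": {r["score"]: r["auroc"] for r in roc_rows},
        "delong_vs_qsofa": {"difference": cmp_q.difference, "p": cmp_q.p_value},
        "delong_vs_severity": {"difference": cmp_s.difference, "p": cmp_s.p_value},
        "kw_significant_bin0": kw.query("bin_index == 0 and kind == 'mean' and significant")[
            "feature"
        ].tolist(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    logger.removeHandler(handler)
    handler.close()
    return report
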