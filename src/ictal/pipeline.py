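"""End-to-end pipeline: input (file or simulation) -> band power ->
detection -> machine-readable JSON report.

The report is fully deterministic: the same config (and seed, for
simulated input) yields a byte-identical JSON document.  Stage timings
go to the log, never into the report.
"""

from __future__ import annotations

import json
import logging
import time

from . import detect as det
from . import io as eio
from . import power as pw
from . import simulate as sim
from .core import EEGRecord

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            logger.info("stage %s finished in %.2f s", name, dt)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _Ctx()


def _load_input(config: dict) -> tuple[EEGRecord, sim.GroundTruth | None]:
    spec = config.get("input")
    if not spec:
        raise ValueError("config must contain an 'input' section")
    if "scenario" in spec:
        sim_config = sim.SimConfig.from_dict(spec["scenario"])
        record, truth = sim.generate_eeg(sim_config)
        return record, truth
    if "se_scenario" in spec:
        s = spec["se_scenario"]
        sim_config = sim.SimConfig.from_dict(s["config"])
        record, truth = sim.generate_se_scenario(
            sim_config, s["se_onset"], s["se_duration"])
        return record, truth
    if "path" in spec:
        record = eio.read_eeg(spec["path"], spec.get("format"),
                              spec.get("sampling_rate"))
        return record, None
    raise ValueError("input must give 'scenario', 'se_scenario' or 'path'")


def run_pipeline(config: dict) -> dict:
    """Run the configured stages and return the report dictionary.

    Config keys: ``input`` (scenario / se_scenario / path), ``profile``
    (``acute``, ``chronic`` or ``none`` to skip detection), ``power``
    (band, epoch_duration, baseline_window in seconds, windows in
    hours), ``baseline_window`` (seconds, for detection).
    """
    report: dict = {"tool": "ictal", "config": config}

    with _stage("input"):
        record, truth = _load_input(config)
        report["input"] = {
            "n_samples": record.n_samples,
            "sampling_rate": record.sampling_rate,
            "duration_s": record.duration,
            "channel": record.channel_label,
        }
        if truth is not None:
            report["input"]["ground_truth"] = {
                "n_spikes": int(truth.spikes.size),
                "n_seizures": len(truth.seizures),
                "n_artifacts": int(truth.artifacts.size),
            }

    pconf = config.get("power", {})
    with _stage("power"):
        band = pconf.get("band", [20.0, 70.0])
        epoch = pconf.get("epoch_duration", 300.0)
        filtered = pw.bandpass(record, pw.FilterSpec(band[0], band[1]))
        series = pw.epoch_power(filtered, epoch)
        if pconf.get("baseline_window"):
            series = pw.relative_power(series,
                                       tuple(pconf["baseline_window"]))
        power_report = {
            "band_hz": [float(band[0]), float(band[1])],
            "epoch_duration_s": float(epoch),
            "n_epochs": series.n_epochs,
            "relative": series.relative,
            "mean_power": round(float(series.power.mean()), 6),
            "epoch_power": [round(float(p), 6) for p in series.power],
        }
        if series.baseline_mean_power is not None:
            power_report["baseline_mean_power"] = round(
                float(series.baseline_mean_power), 6)
        for window in pconf.get("windows", []):
            summary = pw.window_mean_power(series, window[0], window[1])
            power_report.setdefault("window_means", []).append({
                "window_h": [float(window[0]), float(window[1])],
                "mean_power": round(summary.mean_power, 6),
                "n_epochs": summary.n_epochs,
            })
        report["power"] = power_report

    profile_name = config.get("profile", "none")
    if profile_name not in ("acute", "chronic", "none"):
        raise PipelineError("detect", f"unknown profile {profile_name!r}")
    if profile_name != "none":
        with _stage("detect"):
            profile = (det.DetectionProfile.acute() if profile_name == "acute"
                       else det.DetectionProfile.chronic())
            dband = config.get("detection", {}).get("band", [1.0, 100.0])
            det_record = pw.bandpass(record,
                                     pw.FilterSpec(dband[0], dband[1]))
            bwin = config.get("baseline_window",
                              [0.0, profile.baseline_duration])
            baseline = det.compute_baseline(det_record, tuple(bwin))
            cleaned, removed = pw.remove_artifact_transients(
                det_record, baseline, multiplier=profile.multiplier)
            spikes = det.detect_spikes(cleaned, baseline, profile)
            events: dict = {
                "profile": profile_name,
                "baseline": {
                    "window_s": [float(bwin[0]), float(bwin[1])],
                    "amplitude_stat_uv": round(baseline.amplitude_stat, 4),
                    "rms_uv": round(baseline.rms, 4),
                },
                "n_artifacts_removed": len(removed),
                "n_spikes": len(spikes),
            }
            if profile_name == "acute":
                onset = det.detect_se_onset(cleaned, baseline, profile)
                events["se_onset_s"] = (None if onset is None
                                        else round(onset, 3))
            else:
                result = det.detect_srs(cleaned, baseline, profile)
                events["seizures"] = [
                    {
                        "onset_s": round(e.onset, 3),
                        "offset_s": round(e.offset, 3),
                        "duration_s": round(e.duration, 3),
                        "criteria": e.criteria,
                    }
                    for e in result.accepted
                ]
                events["n_accepted"] = len(result.accepted)
                events["n_rejected"] = len(result.rejected)
            report["events"] = events
    return report


def report_json(report: dict) -> str:
    """Canonical JSON rendering of a report (deterministic bytes)."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
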