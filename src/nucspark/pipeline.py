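"""End-to-end simulate -> detect -> segment -> classify -> summarize pipeline.

A :class:`PipelineConfig` (usually loaded from YAML) describes one or more
simulated fibers plus detection/classification parameters.  ``run_pipeline``
executes every stage, writes all tables and QC artifacts into a run
directory, and is fully deterministic for a fixed config and seed.  Any
stage failure aborts with an error naming the stage; partial outputs are
kept next to a ``FAILED`` marker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierParams, classify_events, detect_ngcs
from .detect import DetectionParams, detect_events_xyt, estimate_baseline
from .nuclei import label_nucleus_locations, segment_fiber, segment_nuclei
from .records import average_frames, estimate_drift, read_record, write_record
from .simulate import (EventSpec, FiberSpec, NucleusSpec, SimConfig,
                       generate_xyt, sample_events)
from .stats import compute_frequency, responder_fractions, summarize_metrics

__all__ = ["PipelineConfig", "FiberRun", "PipelineError", "run_pipeline",
           "demo_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class FiberRun:
    """Simulation spec for one fiber dataset in a pipeline run."""

    name: str
    sim: SimConfig
    n_random_events: int = 0
    event_amplitude_rel: float = 0.8
    event_amplitude_sd: float = 0.0
    event_fwhm_um: float = 2.3
    event_fwhm_sd: float = 0.0
    event_duration_frames: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    fibers: tuple[FiberRun, ...]
    detection: DetectionParams = field(default_factory=DetectionParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    condition: str = "hypertonic"
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config stage: file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        fibers = []
        for fr in raw.get("fibers", []):
            sim_raw = dict(fr.get("sim", {}))
            if "fiber" in sim_raw:
                sim_raw["fiber"] = FiberSpec(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sim_raw["fiber"].items()})
            if "nuclei" in sim_raw:
                sim_raw["nuclei"] = tuple(
                    NucleusSpec(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in n.items()})
                    for n in sim_raw["nuclei"])
            if "events" in sim_raw:
                sim_raw["events"] = tuple(
                    EventSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in e.items()})
                    for e in sim_raw["events"])
            fibers.append(FiberRun(
                name=fr["name"], sim=SimConfig(**sim_raw),
                **{k: v for k, v in fr.items() if k not in ("name", "sim")}))
        return PipelineConfig(
            fibers=tuple(fibers),
            detection=DetectionParams(**raw.get("detection", {})),
            classifier=ClassifierParams(**raw.get("classifier", {})),
            condition=raw.get("condition", "hypertonic"),
            seed=int(raw.get("seed", 0)),
        )


def demo_config(seed: int = 7) -> PipelineConfig:
    """Bundled end-to-end fixture: two fibers, five nuclei, 40 events.

    Frames are 256 x 256 px (0.2 um pixels) to keep the demo fast while
    preserving the acquisition geometry; events use study-scale amplitude
    and width (mean FWHM 2.3 um, relative amplitude 0.8).
    """
    common = dict(image_width_px=256, image_height_px=256, n_frames=50,
                  baseline_intensity=40.0, read_noise_sd=2.0, shot_noise=True)
    fiber_a = FiberSpec(center_um=(25.6, 25.6), size_um=(44.0, 30.0))
    fiber_b = FiberSpec(center_um=(25.6, 25.6), size_um=(40.0, 34.0))
    return PipelineConfig(
        fibers=(
            FiberRun(name="fiber_a",
                     sim=SimConfig(fiber=fiber_a, seed=seed, nuclei=(
                         NucleusSpec(center_um=(14.0, 20.0)),
                         NucleusSpec(center_um=(36.0, 30.0)),
                         NucleusSpec(center_um=(26.0, 14.5)),
                     ), **common),
                     n_random_events=22),
            FiberRun(name="fiber_b",
                     sim=SimConfig(fiber=fiber_b, seed=seed + 1, nuclei=(
                         NucleusSpec(center_um=(16.0, 31.0)),
                         NucleusSpec(center_um=(33.0, 17.0)),
                     ), **common),
                     n_random_events=18),
        ),
        seed=seed,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"{name} stage: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate_fiber(run: FiberRun, outdir: Path, seed: int):
    sim = run.sim
    if run.n_random_events:
        rng = np.random.default_rng(seed)
        extra = sample_events(
            sim.fiber, run.n_random_events, rng, sim.n_frames,
            amplitude_rel=run.event_amplitude_rel,
            amplitude_sd=run.event_amplitude_sd,
            fwhm_um=run.event_fwhm_um, fwhm_sd=run.event_fwhm_sd,
            duration_frames=run.event_duration_frames)
        sim = SimConfig(**{**{k: getattr(sim, k) for k in sim.__dataclass_fields__},
                           "events": sim.events + extra})
    channels, truth = generate_xyt(sim)
    for label, rec in channels.items():
        write_record(rec, outdir / f"{run.name}_{label.lower()}.tif")
    truth.events.to_csv(outdir / f"{run.name}_ground_truth.csv", index=False)
    return channels, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full pipeline; returns the run directory.

    Writes, per run: ``events.csv``, ``classified.csv``, ``nuclei.csv``,
    ``summary.json``, ``qc.json`` and ``run_log.json`` (plus per-fiber TIFFs
    and ground-truth tables).  Identical config + seed reproduce identical
    outputs byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classified_rows, event_rows, nuclei_rows, qc = [], [], [], {}
    try:
        for i, run in enumerate(config.fibers):
            channels, truth = _simulate_fiber(run, outdir, config.seed + 1000 + i)
            ca, dna = channels["Ca"], channels["DNA"]
            # round-trip through disk so the I/O path is part of every run
            ca = read_record(outdir / f"{run.name}_ca.tif")
            structural = _stage("average_frames")(average_frames)(dna, n=8)
            tail = average_frames(
                type(dna)(pixels=dna.pixels[-8:], modality="xyt",
                          pixel_size_um=dna.pixel_size_um,
                          frame_interval_s=dna.frame_interval_s,
                          channel=dna.channel), n=8)
            drift = _stage("drift_qc")(estimate_drift)(structural, tail)
            qc[run.name] = {"drift_um": round(drift.shift_um, 4),
                            "drift_exceeds_threshold": drift.exceeds_threshold,
                            "saturated_px_ca": ca.n_saturated_px}
            nuclei = _stage("segment")(segment_nuclei)(structural)
            fiber_mask = _stage("segment")(segment_fiber)(
                average_frames(ca, n=8))
            label_nucleus_locations(nuclei, fiber_mask)
            baseline = _stage("detect")(estimate_baseline)(
                ca, config.detection.baseline_percentile)
            events = _stage("detect")(detect_events_xyt)(
                ca, config.detection, fiber_mask.mask, baseline)
            classified = _stage("classify")(classify_events)(
                events, nuclei, config.classifier)
            ngcs = []
            for nuc in nuclei:
                ngcs.extend(_stage("classify")(detect_ngcs)(
                    ca, nuc, baseline, config.classifier))
            for nuc in nuclei:
                cx, cy = nuc.centroid_xy_um
                nuclei_rows.append(dict(
                    fiber_id=run.name, nucleus_id=nuc.nucleus_id,
                    x_um=round(cx, 3), y_um=round(cy, 3),
                    area_um2=round(nuc.area_um2, 3),
                    location_class=nuc.location_class))
            duration = ca.n_frames * ca.frame_interval_s
            nuc_area = sum(n.area_um2 for n in nuclei)
            for ce in classified:
                ev = ce.event
                row = dict(fiber_id=run.name, event_id=ev.event_id,
                           frame=ev.frame_index, time_s=round(ev.time_s, 4),
                           x_um=round(ev.centroid_xy_um[0], 3),
                           y_um=round(ev.centroid_xy_um[1], 3),
                           amplitude_rel=round(ev.amplitude_rel, 4),
                           fwhm_um=round(ev.fwhm_um, 4), area_px=ev.area_px,
                           fit_quality=round(ev.fit_quality, 4))
                event_rows.append(row)
                classified_rows.append({**row, "label": ce.label,
                                        "nucleus_id": ce.nucleus_id,
                                        "distance_um": round(ce.distance_um, 4)
                                        if np.isfinite(ce.distance_um) else -1})
            for ng in ngcs:
                classified_rows.append(dict(
                    fiber_id=run.name, event_id=-1, frame=-1,
                    time_s=round(ng.onset_s, 4), x_um=-1, y_um=-1,
                    amplitude_rel=round(ng.peak_amplitude_rel, 4),
                    fwhm_um=-1, area_px=-1, fit_quality=-1,
                    label="NGCS", nucleus_id=ng.nucleus_id, distance_um=0.0))
            qc[run.name]["frequency"] = {
                "cell": compute_frequency(len(classified), fiber_mask.area_um2,
                                          duration).frequency_per_1000um2_s,
                "nucleus": (compute_frequency(
                    sum(c.label == "NLCS" for c in classified), nuc_area,
                    duration).frequency_per_1000um2_s if nuc_area else None),
                "cytosol": compute_frequency(
                    sum(c.label == "CLCS" for c in classified),
                    fiber_mask.area_um2 - nuc_area,
                    duration).frequency_per_1000um2_s,
            }
        events_df = pd.DataFrame(event_rows)
        classified_df = pd.DataFrame(classified_rows)
        nuclei_df = pd.DataFrame(nuclei_rows)
        events_df.to_csv(outdir / "events.csv", index=False)
        classified_df.to_csv(outdir / "classified.csv", index=False)
        nuclei_df.to_csv(outdir / "nuclei.csv", index=False)

        fractions = _stage("stats")(responder_fractions)(
            classified_df, n_total=len(config.fibers),
            condition=config.condition, unit="fiber")
        summary = {
            "condition": config.condition,
            "n_fibers": len(config.fibers),
            "n_events": int(len(events_df)),
            "responder_fractions_pct": {
                f.event_class: f.fraction_pct_rounded for f in fractions},
            "frequencies_per_1000um2_s": {
                name: {k: (round(v, 5) if v is not None else None)
                       for k, v in q["frequency"].items()}
                for name, q in qc.items()},
        }
        if len(events_df):
            for metric in ("fwhm_um", "amplitude_rel"):
                ms = summarize_metrics(events_df[metric], metric)
                summary[metric] = {"n": ms.n, "mean": round(ms.mean, 4),
                                   "sem": round(ms.sem, 4)}
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        (outdir / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
        (outdir / "run_log.json").write_text(json.dumps(
            {"nucspark_version": __version__, "seed": config.seed,
             "detection": asdict(config.detection),
             "classifier": asdict(config.classifier)},
            indent=1, sort_keys=True))
    except PipelineError:
        (outdir / "FAILED").write_text("pipeline aborted; see traceback")
        raise
    return outdir
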