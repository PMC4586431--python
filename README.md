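# nucspark

Detection and nucleus-relative classification of localized Ca²⁺ signals
(LCSs) in fluorescence time-lapse recordings of skeletal muscle fibers.

Skeletal muscle fibers produce transient, micrometer-scale Ca²⁺ release
events ("sparks"). When a DNA-dye channel is recorded alongside the Ca²⁺
indicator, each event can be placed relative to the cell nuclei:
intranuclear (**NLCS** — centroid inside a nucleus mask), perinuclear
(**PLCS** — centroid within 2 μm of the nucleus boundary), or cytosolic
(**CLCS**). Whole-nucleus fluorescence rises are detected separately as
global nuclear signals (**NGCS**), and the union of NLCS and NGCS responders
forms the intranuclear class (**INCS**). `nucspark` implements this entire
analysis as a tested, reusable library plus CLI, together with a seeded
synthetic-microscopy generator that provides ground truth for every stage.

## What it computes

* **Event detection** (`nucspark.detect`) — per-pixel baseline F₀ (temporal
  percentile) and noise SD; candidate pixels with
  F > F₀ + *c*·SD (default *c* = 3.6); connected components with ≥ 10
  suprathreshold pixels fitted with a 2-D Gaussian + offset, kept when the
  fit's R² ≥ 0.5. Events report amplitude (F − F₀)/F₀,
  FWHM = 2√(2 ln 2)·√(σₓσᵧ), and — for line scans — the full duration at
  half maximum (FDHM) with linear interpolation.
* **Nucleus segmentation** (`nucspark.nuclei`) — Otsu threshold on the
  smoothed DNA channel (or inverted membrane-dye channel), hole filling,
  area filter; Euclidean distance from any point to the nearest nucleus
  boundary via distance transforms.
* **Classification** (`nucspark.classify`) — the NLCS/PLCS/CLCS partition,
  NGCS runs on whole-nucleus traces, and axial containment verification: an
  event is demonstrably intranuclear when DNA signal overlaps its footprint
  in planes at least

      d_m = ½ (r_ax,Ca + Δr_ax,Ca + r_ax,DNA + Δr_ax,DNA)

  above **and** below its focal plane, where r_ax ± Δr_ax are the two
  channels' axial resolutions (`nucspark.resolution` estimates them from
  bead z-stacks).
* **Statistics** (`nucspark.stats`) — event frequencies in
  events/(1000 μm²·s), responder fractions per fiber and per nucleus,
  metric means ± S.E.M., frequencies normalized to a control condition, and
  algorithm-vs-experimenter agreement.
* **Simulation** (`nucspark.simulate`) — two-channel xyt movies, xt line
  scans, bead z-stacks and nucleus z-stacks with exact ground-truth tables,
  using the acquisition geometry of the analysis (512² px frames,
  ~0.2 μm pixels, 0.82 s/frame; 0.063 μm line scans at 800 lines/s).

## Worked example

Run the bundled end-to-end fixture (two simulated fibers, five nuclei,
40 injected events):

```sh
nucspark run --seed 7 --out demo_out
```

`demo_out/summary.json` then contains (abridged):

```json
{
 "n_events": 37,
 "fwhm_um":       {"mean": 2.2746, "sem": 0.0136, "n": 37},
 "amplitude_rel": {"mean": 0.9497, "sem": 0.0233, "n": 37},
 "responder_fractions_pct": {"CLCS": 100, "PLCS": 100, "NLCS": 50,
                             "NGCS": 0, "INCS": 50},
 "frequencies_per_1000um2_s": {
  "fiber_b": {"cell": 0.30489, "cytosol": 0.2633, "nucleus": 0.38666}
 }
}
```

37 of the 40 injected events are recovered; the mean FWHM (2.27 μm) matches
the configured event width (2.3 μm) to ~1%, and both fibers respond with
cytosolic and perinuclear events while one of the two contains an
intranuclear event (hence 50% NLCS/INCS responder fractions).
`events.csv`, `classified.csv`, `nuclei.csv` and `qc.json` (drift check,
saturation counts) sit alongside. The same library calls are available in
Python via `nucspark.demo_config` / `nucspark.run_pipeline`.

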