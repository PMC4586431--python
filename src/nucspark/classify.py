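"""Nucleus-relative classification of detected Ca2+ events.

Every localized event receives exactly one compartment label:

* ``NLCS`` — intranuclear: the event centroid lies inside a nucleus mask
  (boundary pixels count as inside);
* ``PLCS`` — perinuclear: the centroid is outside every nucleus but within
  ``plcs_distance_um`` (2 um by default, inclusive) of the nearest nucleus
  boundary;
* ``CLCS`` — cytosolic: everything else.

Distances are measured to the nucleus boundary, not its centroid, so the
2 um rule does not depend on nucleus size.  Global nuclear signals (NGCSs)
are detected on the whole-nucleus fluorescence trace, and intranuclear
location of an event can be verified in a z-stack of the DNA channel via the
minimal axial distance d_m: the DNA signal must overlap the event footprint
in at least one plane at least d_m above AND one at least d_m below the
event's focal plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters

from .detect import Baseline, SparkEvent
from .nuclei import NucleusMask, distance_to_nucleus
from .records import ImageRecord
from .resolution import ContainmentCriterion

__all__ = [
    "ClassifierParams",
    "ClassifiedEvent",
    "NgcsEvent",
    "classify_events",
    "detect_ngcs",
    "verify_axial_containment",
    "DEFAULT_PLCS_DISTANCE_UM",
]

DEFAULT_PLCS_DISTANCE_UM = 2.0


@dataclass(frozen=True)
class ClassifierParams:
    plcs_distance_um: float = DEFAULT_PLCS_DISTANCE_UM
    ngcs_amplitude_threshold: float = 0.2
    ngcs_coverage_fraction: float = 0.8
    ngcs_min_frames: int = 2

    def __post_init__(self) -> None:
        if self.plcs_distance_um <= 0:
            raise ValueError("plcs_distance_um must be > 0")
        if not 0 < self.ngcs_coverage_fraction <= 1:
            raise ValueError("ngcs_coverage_fraction must be in (0, 1]")
        if self.ngcs_min_frames < 1:
            raise ValueError("ngcs_min_frames must be >= 1")


@dataclass
class ClassifiedEvent:
    event: SparkEvent
    label: str  # "NLCS" | "PLCS" | "CLCS"
    nucleus_id: int | None
    distance_um: float
    z_verified: str | None = None


@dataclass
class NgcsEvent:
    nucleus_id: int
    onset_s: float
    duration_s: float
    peak_amplitude_rel: float
    oscillatory: bool = False


def classify_events(
    events: list[SparkEvent],
    nuclei: list[NucleusMask],
    params: ClassifierParams | None = None,
) -> list[ClassifiedEvent]:
    """Partition events into NLCS / PLCS / CLCS by centroid position.

    With an empty nucleus list every event is CLCS with infinite distance
    (and a warning): there is nothing to be nuclear relative to.
    """
    params = params or ClassifierParams()
    if not nuclei:
        warnings.warn("no nuclei supplied: all events classified CLCS")
        return [ClassifiedEvent(event=ev, label="CLCS", nucleus_id=None,
                                distance_um=np.inf) for ev in events]
    out: list[ClassifiedEvent] = []
    for ev in events:
        dist, nid, inside = distance_to_nucleus(ev.centroid_xy_um, nuclei)
        if inside:
            out.append(ClassifiedEvent(ev, "NLCS", nid, 0.0))
        elif dist <= params.plcs_distance_um:
            out.append(ClassifiedEvent(ev, "PLCS", nid, dist))
        else:
            out.append(ClassifiedEvent(ev, "CLCS", nid, dist))
    return out


def detect_ngcs(
    record: ImageRecord,
    nucleus: NucleusMask,
    baseline: Baseline,
    params: ClassifierParams | None = None,
) -> list[NgcsEvent]:
    """Detect global nuclear Ca2+ signals on a whole-nucleus trace.

    The per-frame trace is the mean (F - F0)/F0 over the nucleus pixels.  An
    NGCS is a maximal run of frames where the trace reaches
    ``ngcs_amplitude_threshold`` AND at least ``ngcs_coverage_fraction`` of
    the nucleus pixels are individually suprathreshold, lasting at least
    ``ngcs_min_frames``.  Two or more runs in one record mark the signal as
    oscillatory.
    """
    params = params or ClassifierParams()
    if record.modality != "xyt":
        raise ValueError("detect_ngcs expects an xyt record")
    if nucleus.mask.sum() < 10:
        raise ValueError("nucleus mask smaller than 10 px")
    f0 = np.maximum(baseline.f0[nucleus.mask], 1e-9)
    vals = (record.pixels[:, nucleus.mask] - baseline.f0[nucleus.mask]) / f0
    trace = vals.mean(axis=1)
    coverage = (vals >= params.ngcs_amplitude_threshold).mean(axis=1)
    active = (trace >= params.ngcs_amplitude_threshold) & \
             (coverage >= params.ngcs_coverage_fraction)
    runs = []
    start = None
    for k, a in enumerate(active):
        if a and start is None:
            start = k
        elif not a and start is not None:
            runs.append((start, k))
            start = None
    if start is not None:
        runs.append((start, len(active)))
    runs = [(s, e) for s, e in runs if e - s >= params.ngcs_min_frames]
    oscillatory = len(runs) >= 2
    dt = record.frame_interval_s
    return [NgcsEvent(nucleus_id=nucleus.nucleus_id, onset_s=s * dt,
                      duration_s=(e - s) * dt,
                      peak_amplitude_rel=float(trace[s:e].max()),
                      oscillatory=oscillatory)
            for s, e in runs]


def verify_axial_containment(
    event_roi: np.ndarray,
    zstack: ImageRecord,
    plane_of_event_z_um: float,
    dm: ContainmentCriterion | float,
    z0_um: float = 0.0,
) -> str:
    """Check whether an event is axially contained in a DNA-positive body.

    Returns ``"verified"`` if DNA-positive pixels (Otsu threshold on the
    stack) overlap the event footprint in at least one plane at
    ``z >= plane + d_m`` and at least one at ``z <= plane - d_m``;
    ``"indeterminate"`` if the stack does not span both distances;
    ``"not_verified"`` otherwise.  The check is monotone: verification at
    d_m implies verification at any smaller distance.

    Parameters
    ----------
    event_roi
        Boolean footprint of the event on the stack's (rows, cols) grid.
    plane_of_event_z_um
        z of the Ca2+ measurement plane, same origin as ``z0_um``.
    z0_um
        z of the first stack plane.
    """
    if zstack.modality != "zstack":
        raise ValueError("verify_axial_containment expects a zstack")
    if event_roi.shape != zstack.pixels.shape[1:]:
        raise ValueError("event ROI does not match the stack footprint")
    if not event_roi.any():
        raise ValueError("empty event ROI")
    d = dm.d_m_um if isinstance(dm, ContainmentCriterion) else float(dm)
    z = z0_um + np.arange(zstack.pixels.shape[0]) * zstack.z_step_um
    if plane_of_event_z_um - d < z[0] - 1e-9 or plane_of_event_z_um + d > z[-1] + 1e-9:
        return "indeterminate"
    thr = filters.threshold_otsu(zstack.pixels)
    dna = zstack.pixels > thr
    overlap = dna[:, event_roi].any(axis=1)
    above = overlap & (z >= plane_of_event_z_um + d - 1e-9)
    below = overlap & (z <= plane_of_event_z_um - d + 1e-9)
    return "verified" if above.any() and below.any() else "not_verified"
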