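"""Seeded synthetic fluorescence microscopy for spark-analysis validation.

This module fabricates the record types the analysis pipeline consumes, with
exact ground truth:

* two-channel xyt time series — a Ca2+ indicator channel carrying localized
  events (transient isotropic 2-D Gaussian intensity increments) or global
  nuclear rises, and a DNA-dye channel marking nucleus ellipses;
* xt line scans with spatial-Gaussian x temporal-pulse events and a known
  full duration at half maximum (FDHM) per event;
* 3-D bead stacks (point sources rendered as 3-D Gaussians) for resolution
  calibration;
* z-stacks of an ellipsoidal nucleus blurred by the axial PSF, for the axial
  containment check.

Geometry is specified in micrometers; pixel (i, j) has its center at
((j + 0.5) * pixel_size, (i + 0.5) * pixel_size) with x rightward and y
downward.  Noise follows the standard confocal model: Poisson shot noise on
the expected counts followed by additive Gaussian read noise; both are
optional and off noise means the arrays are exactly the expected image.
A :class:`SimConfig` plus its seed fully determines every output bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import ImageRecord

__all__ = [
    "FiberSpec",
    "NucleusSpec",
    "EventSpec",
    "LineScanEventSpec",
    "SimConfig",
    "LineScanConfig",
    "GroundTruth",
    "generate_xyt",
    "generate_xt",
    "generate_bead_stack",
    "generate_nucleus_zstack",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FiberSpec:
    """Fiber footprint: an axis-aligned rectangle or an ellipse, in um."""

    shape: str = "rectangle"  # "rectangle" | "ellipse"
    center_um: tuple[float, float] = (51.2, 51.2)
    size_um: tuple[float, float] = (92.0, 40.0)  # full extents (rect) / axes (ellipse)

    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        cx, cy = self.center_um
        hx, hy = self.size_um[0] / 2.0, self.size_um[1] / 2.0
        if self.shape == "rectangle":
            return (np.abs(x_um - cx) <= hx) & (np.abs(y_um - cy) <= hy)
        if self.shape == "ellipse":
            return ((x_um - cx) / hx) ** 2 + ((y_um - cy) / hy) ** 2 <= 1.0
        raise ValueError(f"unknown fiber shape {self.shape!r}")


@dataclass(frozen=True)
class NucleusSpec:
    """Elliptical nucleus cross-section (semi-axes in um); semi_axis_z_um is
    only used when the nucleus is extruded into 3-D (z-stacks)."""

    center_um: tuple[float, float]
    semi_axes_um: tuple[float, float] = (5.0, 2.0)
    semi_axis_z_um: float = 3.0

    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        cx, cy = self.center_um
        a, b = self.semi_axes_um
        return ((x_um - cx) / a) ** 2 + ((y_um - cy) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class EventSpec:
    """One injected Ca2+ event in an xyt record.

    ``kind="spark"`` renders an isotropic 2-D Gaussian increment of peak
    height ``baseline * amplitude_rel`` and the given spatial FWHM, constant
    over ``duration_frames`` (or linearly decaying with
    ``temporal_profile="decay"``).  ``kind="ngcs"`` renders a uniform rise of
    ``baseline * amplitude_rel`` over the entire nucleus ``nucleus_index``.
    """

    center_xy_um: tuple[float, float]
    onset_frame: int
    duration_frames: int = 1
    amplitude_rel: float = 0.8
    fwhm_um: float = 2.3
    kind: str = "spark"  # "spark" | "ngcs"
    temporal_profile: str = "rect"  # "rect" | "decay"
    nucleus_index: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude_rel <= 0:
            raise ValueError("amplitude_rel must be > 0")
        if self.fwhm_um <= 0:
            raise ValueError("fwhm_um must be > 0")
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be >= 1")
        if self.kind == "ngcs" and self.nucleus_index is None:
            raise ValueError("ngcs events must name a nucleus_index")
        if self.kind not in ("spark", "ngcs"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class LineScanEventSpec:
    """One event in an xt line scan: spatial Gaussian x temporal pulse.

    ``temporal_profile="rect"`` has true FDHM equal to ``duration_s``;
    ``"triangle"`` is a symmetric triangle of base ``duration_s`` whose
    half-maximum crossings are ``duration_s / 2`` apart.
    """

    position_um: float
    onset_s: float
    duration_s: float
    amplitude_rel: float = 1.0
    fwhm_um: float = 1.5
    temporal_profile: str = "rect"  # "rect" | "triangle"

    @property
    def true_fdhm_ms(self) -> float:
        if self.temporal_profile == "rect":
            return 1000.0 * self.duration_s
        if self.temporal_profile == "triangle":
            return 500.0 * self.duration_s
        raise ValueError(f"unknown temporal profile {self.temporal_profile!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for simulated xyt records.

    Geometry and timing mirror the acquisition this package analyses:
    512 x 512 px frames, 0.2 um pixels, 0.82 s per frame, 8-bit counts.
    """

    image_width_px: int = 512
    image_height_px: int = 512
    pixel_size_um: float = 0.2
    frame_interval_s: float = 0.82
    n_frames: int = 60
    fiber: FiberSpec = field(default_factory=FiberSpec)
    nuclei: tuple[NucleusSpec, ...] = ()
    baseline_intensity: float = 30.0
    background_intensity: float = 8.0
    dna_nucleus_factor: float = 4.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    events: tuple[EventSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "events", tuple(self.events))

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.image_width_px) + 0.5) * self.pixel_size_um
        y = (np.arange(self.image_height_px) + 0.5) * self.pixel_size_um
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class LineScanConfig:
    """Line-scan (xt) variant: 512 px spatial line, 0.063 um pixels,
    800 lines/s by default."""

    n_px: int = 512
    pixel_size_um: float = 0.063
    line_interval_s: float = 1.0 / 800.0
    n_lines: int = 8000  # 10 s at 800 lines/s; events are sparse in time
    baseline_intensity: float = 30.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    events: tuple[LineScanEventSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))


@dataclass
class GroundTruth:
    """Per-realization truth: one table row per injected event, the noiseless
    nucleus label image (0 = background, 1..n = nuclei), and the fiber mask."""

    events: pd.DataFrame
    nucleus_labels: np.ndarray | None = None
    fiber_mask: np.ndarray | None = None
    pixel_size_um: float | None = None

    @property
    def compartment_counts(self) -> dict[str, int]:
        if "compartment" not in self.events.columns or self.events.empty:
            return {}
        return self.events["compartment"].value_counts().to_dict()


def sample_events(
    fiber: FiberSpec,
    n: int,
    rng: np.random.Generator,
    n_frames: int,
    amplitude_rel: float = 0.8,
    amplitude_sd: float = 0.0,
    fwhm_um: float = 2.3,
    fwhm_sd: float = 0.0,
    duration_frames: int = 2,
    margin_um: float = 2.0,
) -> tuple[EventSpec, ...]:
    """Draw ``n`` spark events uniformly inside the fiber (with an inner
    margin), at uniform onset frames, with optionally dispersed amplitude
    and FWHM.  Useful for building study-scale populations."""
    cx, cy = fiber.center_um
    hx = fiber.size_um[0] / 2.0 - margin_um
    hy = fiber.size_um[1] / 2.0 - margin_um
    events = []
    while len(events) < n:
        x = cx + rng.uniform(-hx, hx)
        y = cy + rng.uniform(-hy, hy)
        if not bool(fiber.contains(np.array(x + margin_um * np.sign(x - cx)),
                                   np.array(y + margin_um * np.sign(y - cy)))):
            continue
        amp = max(amplitude_rel + rng.normal(0.0, amplitude_sd), 0.05)
        fwhm = max(fwhm_um + rng.normal(0.0, fwhm_sd), 0.5)
        onset = int(rng.integers(1, max(n_frames - duration_frames, 2)))
        events.append(EventSpec(center_xy_um=(x, y), onset_frame=onset,
                                duration_frames=duration_frames,
                                amplitude_rel=amp, fwhm_um=fwhm))
    return tuple(events)


def _apply_noise(expected: np.ndarray, rng: np.random.Generator,
                 shot_noise: bool, read_noise_sd: float) -> np.ndarray:
    out = rng.poisson(expected).astype(float) if shot_noise else expected.copy()
    if read_noise_sd > 0:
        out += rng.normal(0.0, read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _nucleus_labels(config: SimConfig) -> np.ndarray:
    xg, yg = config.pixel_centers_um()
    labels = np.zeros((config.image_height_px, config.image_width_px), dtype=np.int32)
    for i, nuc in enumerate(config.nuclei, start=1):
        inside = nuc.contains(xg, yg)
        if labels[inside].any():
            raise ValueError(f"nucleus {i} overlaps another nucleus")
        labels[inside] = i
    return labels


def _true_compartments(config: SimConfig, labels: np.ndarray,
                       fiber_mask: np.ndarray) -> list[dict]:
    # Label each injected event with the same geometric rules the classifier
    # applies (inside mask -> nuclear; boundary distance <= 2 um -> perinuclear),
    # so truth and classification close the loop on identical geometry.
    from .classify import DEFAULT_PLCS_DISTANCE_UM
    from .nuclei import distance_to_nucleus, masks_from_labels

    nuclei = masks_from_labels(labels, config.pixel_size_um)
    rows = []
    for eid, ev in enumerate(config.events):
        if ev.kind == "ngcs":
            nuc = config.nuclei[ev.nucleus_index]
            rows.append(dict(center=nuc.center_um, compartment="NGCS",
                             nucleus_id=ev.nucleus_index + 1, distance_um=0.0))
            continue
        if nuclei:
            dist, nid, inside = distance_to_nucleus(ev.center_xy_um, nuclei)
        else:
            dist, nid, inside = np.inf, None, False
        if inside:
            label = "NLCS"
        elif dist <= DEFAULT_PLCS_DISTANCE_UM:
            label = "PLCS"
        else:
            label = "CLCS"
        rows.append(dict(center=ev.center_xy_um, compartment=label,
                         nucleus_id=nid, distance_um=float(dist)))
    return rows


def generate_xyt(config: SimConfig) -> tuple[dict[str, ImageRecord], GroundTruth]:
    """Render a two-channel xyt recording and its ground truth.

    Returns ``{"Ca": record, "DNA": record}`` plus a :class:`GroundTruth`
    whose event table carries realized pixel coordinates and the true
    compartment of every event.

    Raises :class:`ValueError` for an event centered outside the fiber.
    """
    xg, yg = config.pixel_centers_um()
    fiber_mask = config.fiber.contains(xg, yg)
    labels = _nucleus_labels(config)
    if np.any(labels.astype(bool) & ~fiber_mask):
        raise ValueError("all nuclei must lie within the fiber geometry")

    shape = (config.n_frames, config.image_height_px, config.image_width_px)
    ca = np.full(shape, float(config.background_intensity))
    ca[:, fiber_mask] = config.baseline_intensity

    for eid, ev in enumerate(config.events):
        frames = range(ev.onset_frame, min(ev.onset_frame + ev.duration_frames,
                                           config.n_frames))
        if ev.kind == "ngcs":
            mask = labels == ev.nucleus_index + 1
            for k in frames:
                ca[k][mask] += config.baseline_intensity * ev.amplitude_rel
            continue
        ex, ey = ev.center_xy_um
        if not config.fiber.contains(np.array(ex), np.array(ey)):
            raise ValueError(f"event {eid} centered at ({ex}, {ey}) um lies "
                             "outside the fiber")
        sigma = ev.fwhm_um / FWHM_PER_SIGMA
        bump = np.exp(-((xg - ex) ** 2 + (yg - ey) ** 2) / (2.0 * sigma**2))
        peak = config.baseline_intensity * ev.amplitude_rel
        for j, k in enumerate(frames):
            if ev.temporal_profile == "decay":
                weight = 1.0 - j / ev.duration_frames
            else:
                weight = 1.0
            ca[k] += peak * weight * bump

    # DNA dye stains only the nuclei: low everywhere else, interior at a
    # configurable multiple of background (segmentation is threshold-free of
    # the exact factor since it is data-driven).
    dna_plane = np.full((config.image_height_px, config.image_width_px),
                        float(config.background_intensity))
    dna_plane[labels > 0] = config.background_intensity * config.dna_nucleus_factor
    dna = np.broadcast_to(dna_plane, shape).copy()

    rng = np.random.default_rng(config.seed)
    ca = _apply_noise(ca, rng, config.shot_noise, config.read_noise_sd)
    dna = _apply_noise(dna, rng, config.shot_noise, config.read_noise_sd)

    compartments = _true_compartments(config, labels, fiber_mask)
    rows = []
    for eid, (ev, comp) in enumerate(zip(config.events, compartments)):
        cx, cy = comp["center"]
        rows.append(dict(
            event_id=eid, kind=ev.kind, x_um=cx, y_um=cy,
            x_px=cx / config.pixel_size_um - 0.5,
            y_px=cy / config.pixel_size_um - 0.5,
            onset_frame=ev.onset_frame, duration_frames=ev.duration_frames,
            amplitude_rel=ev.amplitude_rel, fwhm_um=ev.fwhm_um,
            compartment=comp["compartment"], nucleus_id=comp["nucleus_id"],
            distance_um=comp["distance_um"],
        ))
    truth = GroundTruth(
        events=pd.DataFrame(rows, columns=[
            "event_id", "kind", "x_um", "y_um", "x_px", "y_px", "onset_frame",
            "duration_frames", "amplitude_rel", "fwhm_um", "compartment",
            "nucleus_id", "distance_um"]),
        nucleus_labels=labels, fiber_mask=fiber_mask,
        pixel_size_um=config.pixel_size_um,
    )
    common = dict(modality="xyt", pixel_size_um=config.pixel_size_um,
                  frame_interval_s=config.frame_interval_s)
    return (
        {"Ca": ImageRecord(pixels=ca, channel="Ca", **common),
         "DNA": ImageRecord(pixels=dna, channel="DNA", **common)},
        truth,
    )


def generate_xt(config: LineScanConfig) -> tuple[ImageRecord, GroundTruth]:
    """Render a single-channel line-scan (time x space) image with known
    per-event FDHM."""
    t = np.arange(config.n_lines)[:, None] * config.line_interval_s
    x = (np.arange(config.n_px)[None, :] + 0.5) * config.pixel_size_um
    img = np.full((config.n_lines, config.n_px), float(config.baseline_intensity))
    rows = []
    for eid, ev in enumerate(config.events):
        if not (0.0 <= ev.position_um <= config.n_px * config.pixel_size_um):
            raise ValueError(f"event {eid} position outside the scanned line")
        sigma = ev.fwhm_um / FWHM_PER_SIGMA
        gx = np.exp(-((x - ev.position_um) ** 2) / (2.0 * sigma**2))
        if ev.temporal_profile == "rect":
            pt = ((t >= ev.onset_s) & (t < ev.onset_s + ev.duration_s)).astype(float)
        elif ev.temporal_profile == "triangle":
            apex = ev.onset_s + ev.duration_s / 2.0
            pt = np.clip(1.0 - np.abs(t - apex) / (ev.duration_s / 2.0), 0.0, 1.0)
        else:
            raise ValueError(f"unknown temporal profile {ev.temporal_profile!r}")
        img += config.baseline_intensity * ev.amplitude_rel * gx * pt
        rows.append(dict(event_id=eid, position_um=ev.position_um,
                         onset_s=ev.onset_s, duration_s=ev.duration_s,
                         amplitude_rel=ev.amplitude_rel, fwhm_um=ev.fwhm_um,
                         fdhm_ms=ev.true_fdhm_ms,
                         temporal_profile=ev.temporal_profile))
    rng = np.random.default_rng(config.seed)
    img = _apply_noise(img, rng, config.shot_noise, config.read_noise_sd)
    record = ImageRecord(pixels=img, modality="xt",
                         pixel_size_um=config.pixel_size_um,
                         line_interval_s=config.line_interval_s, channel="Ca")
    truth = GroundTruth(events=pd.DataFrame(rows, columns=[
        "event_id", "position_um", "onset_s", "duration_s", "amplitude_rel",
        "fwhm_um", "fdhm_ms", "temporal_profile"]))
    return record, truth


def generate_bead_stack(
    lateral_fwhm_um: float,
    axial_fwhm_um: float,
    n_beads: int,
    z_step_um: float = 0.2,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    field_um: float = 25.0,
    n_planes: int = 61,
    amplitude: float = 150.0,
    background: float = 10.0,
    read_noise_sd: float = 0.0,
    shot_noise: bool = False,
) -> tuple[ImageRecord, np.ndarray]:
    """Render a z-stack of sub-resolution beads as 3-D Gaussians.

    Beads emulate 0.1 um microspheres: each is a point source imaged as a
    separable Gaussian with the requested lateral and axial FWHM.  Centers
    are laid on a jittered grid with pairwise lateral separation of at least
    five lateral FWHM, so neighboring beads cannot bias each other's fits.

    Returns the stack and the true centers as an ``(n, 3)`` array of
    ``(x_um, y_um, z_um)`` with z measured from the first plane.
    """
    if lateral_fwhm_um <= 0 or axial_fwhm_um <= 0:
        raise ValueError("FWHMs must be > 0")
    rng = np.random.default_rng(seed)
    min_sep = 5.0 * lateral_fwhm_um
    margin = 3.0 * lateral_fwhm_um
    centers = []
    if n_beads > 0:
        usable = field_um - 2 * margin
        n_grid = int(usable // min_sep) + 1
        if n_grid * n_grid < n_beads:
            raise ValueError(
                f"cannot place {n_beads} beads with >= {min_sep:.2f} um "
                f"separation in a {field_um} um field")
        slots = [(margin + i * min_sep, margin + j * min_sep)
                 for i in range(n_grid) for j in range(n_grid)]
        picks = rng.choice(len(slots), size=n_beads, replace=False)
        z_mid = (n_planes - 1) / 2.0 * z_step_um
        for p in picks:
            gx, gy = slots[p]
            jitter = rng.uniform(-0.4, 0.4, size=3)
            centers.append((gx + jitter[0] * pixel_size_um,
                            gy + jitter[1] * pixel_size_um,
                            z_mid + jitter[2] * z_step_um))
    centers = np.array(centers, dtype=float).reshape(-1, 3)

    n_px = int(round(field_um / pixel_size_um))
    x = (np.arange(n_px) + 0.5) * pixel_size_um
    z = np.arange(n_planes) * z_step_um
    xg, yg = np.meshgrid(x, x)
    sig_l = lateral_fwhm_um / FWHM_PER_SIGMA
    sig_a = axial_fwhm_um / FWHM_PER_SIGMA
    stack = np.full((n_planes, n_px, n_px), float(background))
    for bx, by, bz in centers:
        lateral = np.exp(-((xg - bx) ** 2 + (yg - by) ** 2) / (2 * sig_l**2))
        axial = np.exp(-((z - bz) ** 2) / (2 * sig_a**2))
        stack += amplitude * axial[:, None, None] * lateral[None, :, :]
    stack = _apply_noise(stack, rng, shot_noise, read_noise_sd)
    record = ImageRecord(pixels=stack, modality="zstack",
                         pixel_size_um=pixel_size_um, z_step_um=z_step_um,
                         channel="beads")
    return record, centers


def generate_nucleus_zstack(
    nucleus_semi_axes_um: tuple[float, float, float],
    z_step_um: float = 0.5,
    pixel_size_um: float = 0.2,
    axial_fwhm_um: float = 1.78,
    center_xy_um: tuple[float, float] | None = None,
    field_um: float = 20.0,
    background: float = 8.0,
    nucleus_intensity: float = 120.0,
    read_noise_sd: float = 0.0,
    shot_noise: bool = False,
    seed: int = 0,
) -> tuple[ImageRecord, float]:
    """Render a DNA-channel z-stack of one ellipsoidal nucleus.

    The ellipsoid interior (semi-axes ``(a, b, c)`` along x, y, z) is filled
    at ``nucleus_intensity`` and blurred along z by a Gaussian axial PSF of
    the given FWHM; the z range spans the ellipsoid plus a 2x axial-FWHM
    margin on each side.  Returns the stack and the z coordinate (um, from
    the first plane) of the ellipsoid center.
    """
    from scipy.ndimage import gaussian_filter1d

    a, b, c = nucleus_semi_axes_um
    if center_xy_um is None:
        center_xy_um = (field_um / 2.0, field_um / 2.0)
    margin = 2.0 * axial_fwhm_um
    half_span = c + margin
    n_half = int(np.ceil(half_span / z_step_um))
    z = np.arange(-n_half, n_half + 1) * z_step_um
    n_px = int(round(field_um / pixel_size_um))
    x = (np.arange(n_px) + 0.5) * pixel_size_um
    xg, yg = np.meshgrid(x, x)
    cx, cy = center_xy_um
    stack = np.full((z.size, n_px, n_px), float(background))
    for k, zk in enumerate(z):
        frac = 1.0 - (zk / c) ** 2
        if frac <= 0:
            continue
        inside = (((xg - cx) / (a * np.sqrt(frac))) ** 2
                  + ((yg - cy) / (b * np.sqrt(frac))) ** 2) <= 1.0
        stack[k][inside] = nucleus_intensity
    sigma_planes = (axial_fwhm_um / FWHM_PER_SIGMA) / z_step_um
    stack = gaussian_filter1d(stack, sigma=sigma_planes, axis=0, mode="nearest")
    rng = np.random.default_rng(seed)
    stack = _apply_noise(stack, rng, shot_noise, read_noise_sd)
    record = ImageRecord(pixels=stack, modality="zstack",
                         pixel_size_um=pixel_size_um, z_step_um=z_step_um,
                         channel="DNA")
    return record, float(n_half * z_step_um)
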