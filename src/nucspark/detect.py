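"""Detection of localized Ca2+ signals (LCSs) in xyt series and xt line scans.

The detector follows the classical spark-detection scheme: a per-pixel
baseline F0 and noise SD are estimated over time, pixels brighter than
``F0 + threshold_coefficient * SD`` form candidate components, components
with at least ``spatial_filter_px`` suprathreshold pixels are fitted with a
2-D Gaussian plus offset, and fits with a coefficient of determination of at
least ``gaussian_fit_threshold`` are emitted as events.  Suprathreshold
components overlapping across consecutive frames are merged into a single
event reported at its peak frame.  Defaults — threshold coefficient 3.6,
Gaussian fit filter 0.5, spatial filter 10 px — are the settings this
detection stage is normally operated with.

Amplitude is the fitted peak of (F - F0)/F0, so it is ratio-based: adding a
constant offset to every pixel changes the amplitude unless F0 shifts by the
same amount.  The raw suprathreshold maximum is stored alongside.  Spatial
FWHM is ``2 sqrt(2 ln 2) sqrt(sigma_x sigma_y)``.  For line scans the full
duration at half maximum (FDHM) is measured on the temporal profile through
the event's spatial center, with linear interpolation between samples; an
event truncated by the record boundary carries a lower-bound flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .records import ImageRecord
from .simulate import FWHM_PER_SIGMA

__all__ = [
    "DetectionParams",
    "Baseline",
    "SparkEvent",
    "LineScanEvent",
    "estimate_baseline",
    "detect_events_xyt",
    "detect_events_xt",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection parameters.

    threshold_coefficient
        Multiple of the per-pixel noise SD above baseline a pixel must reach.
    gaussian_fit_threshold
        Minimum coefficient of determination (R^2) of the 2-D Gaussian fit.
    spatial_filter_px
        Minimum suprathreshold pixel count of a component (in its peak frame).
    baseline_percentile
        Temporal percentile used for the per-pixel F0 map.
    """

    threshold_coefficient: float = 3.6
    gaussian_fit_threshold: float = 0.5
    spatial_filter_px: int = 10
    baseline_percentile: float = 20.0

    def __post_init__(self) -> None:
        if self.threshold_coefficient <= 0:
            raise ValueError("threshold_coefficient must be > 0")
        if self.spatial_filter_px < 1:
            raise ValueError("spatial_filter_px must be >= 1")
        if not 0.0 <= self.gaussian_fit_threshold <= 1.0:
            raise ValueError("gaussian_fit_threshold must be in [0, 1]")


@dataclass
class Baseline:
    """Per-pixel baseline F0 and noise SD maps."""

    f0: np.ndarray
    sd: np.ndarray


@dataclass
class SparkEvent:
    """One detected localized Ca2+ signal in an xyt record."""

    event_id: int
    centroid_xy_um: tuple[float, float]
    frame_index: int
    time_s: float
    amplitude_rel: float
    fwhm_um: float
    area_px: int
    fit_quality: float
    raw_peak_rel: float
    n_frames_merged: int = 1
    source_modality: str = "xyt"


@dataclass
class LineScanEvent:
    """One detected event in an xt line scan."""

    event_id: int
    position_um: float
    onset_s: float
    fdhm_ms: float
    amplitude_rel: float
    spatial_fwhm_um: float
    area_px: int
    fdhm_is_lower_bound: bool = False
    source_modality: str = "xt"


def estimate_baseline(record: ImageRecord, percentile: float = 20.0) -> Baseline:
    """Estimate per-pixel baseline and noise SD from the time axis.

    F0 is the temporal ``percentile`` (20th by default), which is robust to
    sparse bright transients.  The SD map comes from temporal residuals:
    a MAD-based robust scale first, then the plain SD of residuals within
    3 robust-sigma of their median, so event frames do not inflate it.
    Requires at least 10 frames/lines.
    """
    if record.modality not in ("xyt", "xt"):
        raise ValueError("estimate_baseline expects an xyt or xt record")
    pix = record.pixels
    if pix.shape[0] < 10:
        raise ValueError("baseline estimation needs >= 10 frames")
    f0 = np.percentile(pix, percentile, axis=0)
    resid = pix - f0
    med = np.median(resid, axis=0)
    sigma0 = 1.4826 * np.median(np.abs(resid - med), axis=0)
    keep = resid - med <= 3.0 * np.maximum(sigma0, 1e-12)
    n_keep = keep.sum(axis=0)
    mean_keep = np.where(n_keep > 0, (resid * keep).sum(axis=0) / np.maximum(n_keep, 1), 0.0)
    var = (((resid - mean_keep) * keep) ** 2).sum(axis=0) / np.maximum(n_keep - 1, 1)
    sd = np.sqrt(var)
    return Baseline(f0=f0, sd=sd)


def _gauss2d(coords, amp, x0, y0, sx, sy, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))
            + offset).ravel()


def _fit_component(dff: np.ndarray, comp_mask: np.ndarray, pad: int = 6):
    """Fit a 2-D Gaussian + offset to (F-F0)/F0 around one component.

    Returns (amp, x0_px, y0_px, fwhm_px, r2) or None for a degenerate fit.
    """
    rows, cols = np.nonzero(comp_mask)
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, dff.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, dff.shape[1])
    win = dff[r0:r1, c0:c1]
    yy, xx = np.mgrid[0:win.shape[0], 0:win.shape[1]]
    peak_r, peak_c = np.unravel_index(np.argmax(win), win.shape)
    sigma0 = max(np.sqrt(comp_mask.sum() / np.pi) / 1.5, 0.8)
    p0 = (float(win.max()), float(peak_c), float(peak_r), sigma0, sigma0, 0.0)
    try:
        popt, _ = curve_fit(
            _gauss2d, (xx, yy), win.ravel(), p0=p0,
            bounds=([0.0, -pad, -pad, 0.3, 0.3, -np.inf],
                    [np.inf, win.shape[1] + pad, win.shape[0] + pad,
                     max(dff.shape), max(dff.shape), np.inf]),
            maxfev=4000,
        )
    except RuntimeError:
        return None
    amp, x0, y0, sx, sy, _ = popt
    if not (0 <= x0 <= win.shape[1] and 0 <= y0 <= win.shape[0]):
        return None
    if max(sx, sy) > max(dff.shape) / 2:
        return None
    model = _gauss2d((xx, yy), *popt)
    ss_res = float(((win.ravel() - model) ** 2).sum())
    ss_tot = float(((win - win.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return amp, c0 + x0, r0 + y0, FWHM_PER_SIGMA * np.sqrt(sx * sy), r2


def detect_events_xyt(
    record: ImageRecord,
    params: DetectionParams | None = None,
    fiber_mask: np.ndarray | None = None,
    baseline: Baseline | None = None,
) -> list[SparkEvent]:
    """Detect localized events in an xyt record.

    Candidate pixels satisfy ``F > F0 + coeff * SD`` inside the fiber mask;
    connected components are linked across consecutive frames when any pixel
    overlaps, and each merged event is measured at its peak frame (largest
    suprathreshold (F-F0)/F0).  Components whose peak-frame area is below
    ``spatial_filter_px``, and fits below the R^2 filter, are discarded.
    Degenerate fits (center off-window, runaway width) are rejected.
    """
    params = params or DetectionParams()
    if record.modality != "xyt":
        raise ValueError("detect_events_xyt expects an xyt record")
    baseline = baseline or estimate_baseline(record, params.baseline_percentile)
    f0 = np.maximum(baseline.f0, 1e-9)
    thr = baseline.f0 + params.threshold_coefficient * baseline.sd
    above = record.pixels > thr
    if fiber_mask is not None:
        above &= fiber_mask
    # 26-connectivity in (t, y, x): merges in-plane 8-neighbours and any
    # pixel overlap (or diagonal touch) across consecutive frames.
    labels, n_comp = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    events: list[SparkEvent] = []
    eid = 0
    dff_cache: dict[int, np.ndarray] = {}
    for comp in range(1, n_comp + 1):
        comp_mask3 = labels == comp
        frames = np.nonzero(comp_mask3.any(axis=(1, 2)))[0]
        # peak frame: largest suprathreshold relative amplitude
        best_frame, best_val = -1, -np.inf
        for k in frames:
            if k not in dff_cache:
                dff_cache[k] = (record.pixels[k] - baseline.f0) / f0
            v = dff_cache[k][comp_mask3[k]].max()
            if v > best_val:
                best_frame, best_val = int(k), float(v)
        peak_mask = comp_mask3[best_frame]
        area = int(peak_mask.sum())
        if area < params.spatial_filter_px:
            continue
        fit = _fit_component(dff_cache[best_frame], peak_mask)
        if fit is None:
            continue
        amp, x_px, y_px, fwhm_px, r2 = fit
        if r2 < params.gaussian_fit_threshold:
            continue
        events.append(SparkEvent(
            event_id=eid,
            centroid_xy_um=((x_px + 0.5) * record.pixel_size_um,
                            (y_px + 0.5) * record.pixel_size_um),
            frame_index=best_frame,
            time_s=best_frame * record.frame_interval_s,
            amplitude_rel=float(amp),
            fwhm_um=float(fwhm_px * record.pixel_size_um),
            area_px=area,
            fit_quality=float(r2),
            raw_peak_rel=best_val,
            n_frames_merged=len(frames),
        ))
        eid += 1
    return events


def _fdhm_from_profile(profile: np.ndarray, peak_idx: int, f0: float,
                       dt_s: float) -> tuple[float, bool]:
    """Width (ms) of a temporal profile at half of (peak - F0), linear
    interpolation between samples; flags truncation at either record edge."""
    dff = profile - f0
    half = dff[peak_idx] / 2.0
    truncated = False
    # walk left
    i = peak_idx
    while i > 0 and dff[i - 1] >= half:
        i -= 1
    if i == 0 and dff[0] >= half:
        left = 0.0
        truncated = True
    else:
        frac = (dff[i] - half) / (dff[i] - dff[i - 1])
        left = i - frac
    j = peak_idx
    n = dff.size
    while j < n - 1 and dff[j + 1] >= half:
        j += 1
    if j == n - 1 and dff[n - 1] >= half:
        right = float(n - 1)
        truncated = True
    else:
        frac = (dff[j] - half) / (dff[j] - dff[j + 1])
        right = j + frac
    return (right - left) * dt_s * 1000.0, truncated


def detect_events_xt(
    record: ImageRecord,
    params: DetectionParams | None = None,
) -> list[LineScanEvent]:
    """Detect events in a line-scan (time x space) image and measure FDHM.

    The threshold rule is the same as for xyt, applied to the 2-D
    space x time image (per-column baseline over time).  FDHM is measured on
    the temporal profile at each event's spatial center.
    """
    params = params or DetectionParams()
    if record.modality != "xt":
        raise ValueError("detect_events_xt expects an xt record")
    baseline = estimate_baseline(record, params.baseline_percentile)
    f0 = np.maximum(baseline.f0, 1e-9)
    above = record.pixels > baseline.f0 + params.threshold_coefficient * baseline.sd
    labels, n_comp = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    dff = (record.pixels - baseline.f0) / f0
    events: list[LineScanEvent] = []
    eid = 0
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        if mask.sum() < params.spatial_filter_px:
            continue
        flat = np.where(mask, dff, -np.inf)
        t_peak, x_peak = np.unravel_index(np.argmax(flat), flat.shape)
        fdhm_ms, truncated = _fdhm_from_profile(
            record.pixels[:, x_peak], t_peak, float(baseline.f0[x_peak]),
            record.line_interval_s)
        # spatial FWHM from a 1-D Gaussian fit at the peak line
        prof = dff[t_peak]
        try:
            from .resolution import _fit_fwhm
            spatial_fwhm = _fit_fwhm(prof, record.pixel_size_um)
        except RuntimeError:
            spatial_fwhm = np.nan
        onset_line = int(np.nonzero(mask.any(axis=1))[0][0])
        events.append(LineScanEvent(
            event_id=eid,
            position_um=(x_peak + 0.5) * record.pixel_size_um,
            onset_s=onset_line * record.line_interval_s,
            fdhm_ms=float(fdhm_ms),
            amplitude_rel=float(dff[t_peak, x_peak]),
            spatial_fwhm_um=float(spatial_fwhm),
            area_px=int(mask.sum()),
            fdhm_is_lower_bound=truncated,
        ))
        eid += 1
    return events
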