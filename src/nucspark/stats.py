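"""Summary statistics for classified Ca2+ events.

Implements the reporting conventions of nucleus-relative spark studies:

* event frequency per compartment in events / (1000 um^2 * s), with the
  nucleus compartment normalized by summed nucleus area and the cytosol by
  fiber-minus-nuclei area;
* responder fractions — the percentage of fibers (or nuclei) showing at
  least one event of a class, with intranuclear signals (INCS) defined as
  the union of localized (NLCS) and global (NGCS) nuclear responders;
* metric means +/- S.E.M. (sd / sqrt(n));
* per-fiber frequencies normalized to a control condition's mean;
* algorithm-vs-experimenter agreement on responder sets.

Report fractions are rounded half-up to whole percent, mirroring how such
tables are printed; raw values are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resolution import round_half_up

__all__ = [
    "FrequencyStats",
    "ResponderSummary",
    "MetricSummary",
    "compute_frequency",
    "responder_fraction",
    "responder_fractions",
    "summarize_metrics",
    "relative_frequency",
    "annotation_agreement",
]

EVENT_CLASSES = ("CLCS", "PLCS", "NLCS", "NGCS", "INCS")


@dataclass(frozen=True)
class FrequencyStats:
    compartment: str  # "nucleus" | "cytosol" | "cell"
    n_events: int
    area_um2: float
    duration_s: float

    @property
    def frequency_per_1000um2_s(self) -> float:
        return self.n_events / (self.area_um2 * self.duration_s) * 1000.0


@dataclass(frozen=True)
class ResponderSummary:
    condition: str
    unit: str  # "fiber" | "nucleus"
    event_class: str
    n_responding: int
    n_total: int

    @property
    def fraction_pct(self) -> float:
        return 100.0 * self.n_responding / self.n_total

    @property
    def fraction_pct_rounded(self) -> int:
        return int(round_half_up(self.fraction_pct, 0))


@dataclass(frozen=True)
class MetricSummary:
    metric: str
    n: int
    mean: float
    sem: float


def compute_frequency(
    events,
    area_um2: float,
    duration_s: float,
    compartment: str = "cell",
) -> FrequencyStats:
    """Event frequency in events / (1000 um^2 * s).

    ``events`` may be an event count or a sized collection.  The caller
    supplies the compartment area: summed nucleus areas for ``"nucleus"``,
    fiber-minus-nuclei for ``"cytosol"``, whole fiber for ``"cell"``.
    """
    n = events if isinstance(events, (int, np.integer)) else len(events)
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    return FrequencyStats(compartment=compartment, n_events=int(n),
                          area_um2=float(area_um2), duration_s=float(duration_s))


def responder_fraction(
    n_responding: int,
    n_total: int,
    condition: str = "",
    unit: str = "fiber",
    event_class: str = "",
) -> ResponderSummary:
    """Fraction of units with at least one event of a class, as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_responding <= n_total:
        raise ValueError("n_responding must be in [0, n_total]")
    return ResponderSummary(condition=condition, unit=unit,
                            event_class=event_class,
                            n_responding=int(n_responding), n_total=int(n_total))


def responder_fractions(
    events: pd.DataFrame,
    n_total: int,
    condition: str = "",
    unit: str = "fiber",
    unit_column: str = "fiber_id",
) -> list[ResponderSummary]:
    """Responder fractions per event class over a universe of units.

    ``events`` needs columns ``label`` and ``unit_column``; a unit responds
    with class X if it has >= 1 event labeled X (duplicates within a unit do
    not change the result).  INCS responders are the union of NLCS and NGCS
    responders.  ``n_total`` is the number of units observed, responding or
    not.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    responders: dict[str, set] = {c: set() for c in EVENT_CLASSES}
    if len(events):
        for label, grp in events.groupby("label"):
            if label in responders:
                responders[label].update(grp[unit_column].unique())
    responders["INCS"] = responders["NLCS"] | responders["NGCS"]
    return [
        ResponderSummary(condition=condition, unit=unit, event_class=c,
                         n_responding=len(responders[c]), n_total=n_total)
        for c in EVENT_CLASSES
    ]


def summarize_metrics(values, metric: str = "") -> MetricSummary:
    """Mean +/- S.E.M. of an event metric (FWHM, amplitude, FDHM, ...)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty metric sample")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return MetricSummary(metric=metric, n=int(arr.size),
                         mean=float(arr.mean()), sem=sem)


def relative_frequency(
    conditions: dict[str, list[float]],
    control: str,
) -> pd.DataFrame:
    """Normalize per-fiber cellular frequencies to the control mean.

    Every per-fiber frequency is divided by the mean frequency of the
    control condition, so the control reports 1.000 +/- its S.E.M. by
    construction.  Returns a table with condition, n, mean and sem of the
    normalized values.
    """
    if control not in conditions or not len(conditions[control]):
        raise ValueError(f"control condition {control!r} missing or empty")
    control_mean = float(np.mean(conditions[control]))
    if control_mean == 0:
        raise ValueError("control mean frequency is zero")
    rows = []
    for cond, vals in conditions.items():
        rel = np.asarray(vals, dtype=float) / control_mean
        sem = float(rel.std(ddof=1) / np.sqrt(rel.size)) if rel.size > 1 else 0.0
        rows.append(dict(condition=cond, n=rel.size,
                         mean_relative=float(rel.mean()), sem_relative=sem))
    return pd.DataFrame(rows)


def annotation_agreement(algorithmic: set, manual: set) -> float:
    """Agreement (%) between algorithmic and manual responder sets.

    Units found by both methods over all manually positive units:
    ``100 * |A & M| / |(A & M) | (M - A)|``.  Units flagged only by the
    algorithm do not enter the denominator — the reference is the manual
    annotation.
    """
    algorithmic, manual = set(algorithmic), set(manual)
    denom = (algorithmic & manual) | (manual - algorithmic)
    if not denom:
        raise ValueError("empty union: no manually positive units")
    return 100.0 * len(algorithmic & manual) / len(denom)
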