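"""Gating and summarizing of large-particle flow-cytometry event tables.

COPAS-style sorters record one row per detected object: time-of-flight
(TOF, an axial-length proxy), extinction (optical density), and
fluorescence channels. Raw tables mix adult worms with larvae, bacterial
debris, worm doublets and curled-up animals; gates on the (TOF,
extinction) plane remove these before any fluorescence statistic is
computed.

Gate thresholds are fully config-driven. Because published gate values
are instrument- and settings-specific, :meth:`GateConfig.from_reference`
derives defaults from the adult medians of an uninjured reference
population: lower bounds at 0.5x the medians, a bacterial-debris box at
0.1x, a doublet bound at 1.7x the median extinction, and a curl region
(short TOF, high extinction) at 0.6x / 1.2x.

Intervals are closed on the left and open on the right: an event sitting
exactly on a lower bound is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._propagation import quotient_with_error
from .errors import ConfigurationError, DataError

__all__ = [
    "GateConfig",
    "GateReport",
    "PopulationSummary",
    "DeadFraction",
    "gate_events",
    "summarize_population",
    "select_percentile",
    "dead_fraction",
    "normalize_timecourse",
]

#: flags are assigned in this fixed order; each event gets its first match only
GATE_ORDER = ("bacteria", "larva", "doublet", "curl")

CHANNELS = ("tof", "extinction", "green", "red")


@dataclass(frozen=True)
class GateConfig:
    """Thresholds defining the clean adult-worm region.

    ``doublet_slope``/``doublet_intercept`` define a linear bound in the
    (TOF, extinction) plane; events strictly above it are doublets.
    """

    tof_min: float
    ext_min: float
    tof_max: float = np.inf
    ext_max: float = np.inf
    bacteria_tof_max: float = 0.0
    bacteria_ext_max: float = 0.0
    doublet_slope: float = 0.0
    doublet_intercept: float = np.inf
    tof_max_curl: float = 0.0
    ext_min_curl: float = np.inf
    red_dead_threshold: float = np.inf

    def __post_init__(self) -> None:
        if not self.tof_min < self.tof_max:
            raise ConfigurationError("tof_min must be < tof_max")
        if not self.ext_min < self.ext_max:
            raise ConfigurationError("ext_min must be < ext_max")

    @classmethod
    def from_reference(
        cls,
        reference_events: pd.DataFrame,
        lower_factor: float = 0.5,
        bacteria_factor: float = 0.1,
        doublet_ext_factor: float = 1.7,
        curl_tof_factor: float = 0.6,
        curl_ext_factor: float = 1.2,
        red_dead_threshold: float = 50.0,
    ) -> "GateConfig":
        """Derive gates from the adult medians of an uninjured reference table."""
        _require_events(reference_events)
        med_tof = float(reference_events["tof"].median())
        med_ext = float(reference_events["extinction"].median())
        return cls(
            tof_min=lower_factor * med_tof,
            ext_min=lower_factor * med_ext,
            bacteria_tof_max=bacteria_factor * med_tof,
            bacteria_ext_max=bacteria_factor * med_ext,
            doublet_slope=0.0,
            doublet_intercept=doublet_ext_factor * med_ext,
            tof_max_curl=curl_tof_factor * med_tof,
            ext_min_curl=curl_ext_factor * med_ext,
            red_dead_threshold=red_dead_threshold,
        )


@dataclass
class GateReport:
    """Counts removed per gate plus per-event flags for audit."""

    n_input: int
    n_retained: int
    removed: dict[str, int]
    n_dead_flagged: int
    #: one label per input event: "" for retained, else the gate name
    flags: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gate": g, "n_removed": self.removed.get(g, 0)} for g in GATE_ORDER]
        rows.append({"gate": "retained", "n_removed": self.n_retained})
        return pd.DataFrame(rows)


def _require_events(events: pd.DataFrame) -> None:
    if events is None or len(events) == 0:
        raise DataError("event table is empty")
    missing = [c for c in ("tof", "extinction") if c not in events.columns]
    if missing:
        raise DataError(f"event table lacks required columns: {missing}")


def gate_events(events: pd.DataFrame, gates: GateConfig) -> tuple[pd.DataFrame, GateReport]:
    """Remove contaminant events, returning the clean table and a report.

    Flags are assigned in the fixed order bacteria -> larva -> doublet ->
    curl; each event receives only its first matching flag. Bacteria fall
    below the debris box on both channels; larvae fail a lower rectangle
    bound on both channels; doublets lie strictly above the linear
    (TOF, extinction) bound; curled worms combine short TOF with high
    extinction. Events above ``red_dead_threshold`` on the red channel are
    counted as propidium-iodide positive but retained (death is a
    measurement, not a contaminant).

    Gating is idempotent: re-gating a gated table removes nothing.
    """
    _require_events(events)
    tof = events["tof"].to_numpy(dtype=float)
    ext = events["extinction"].to_numpy(dtype=float)
    g = gates

    flags = np.full(len(events), "", dtype=object)
    unassigned = np.ones(len(events), dtype=bool)

    rules = {
        "bacteria": (tof < g.bacteria_tof_max) & (ext < g.bacteria_ext_max),
        "larva": (tof < g.tof_min) & (ext < g.ext_min),
        "doublet": (ext > g.doublet_slope * tof + g.doublet_intercept)
        | (tof >= g.tof_max)
        | (ext >= g.ext_max),
        "curl": (tof < g.tof_max_curl) & (ext > g.ext_min_curl),
    }
    for name in GATE_ORDER:
        hit = unassigned & rules[name]
        flags[hit] = name
        unassigned &= ~hit

    retained = events.loc[unassigned].copy()
    removed = {name: int((flags == name).sum()) for name in GATE_ORDER}
    if len(retained) == 0:
        dominant = max(removed, key=removed.get)
        raise DataError(
            f"all {len(events)} events were gated out (dominant gate: {dominant})"
        )
    n_dead = 0
    if "red" in retained.columns and np.isfinite(g.red_dead_threshold):
        n_dead = int((retained["red"].to_numpy(dtype=float) > g.red_dead_threshold).sum())
    report = GateReport(
        n_input=len(events),
        n_retained=len(retained),
        removed=removed,
        n_dead_flagged=n_dead,
        flags=pd.Series(flags, index=events.index, name="gate_flag"),
    )
    return retained, report


@dataclass(frozen=True)
class PopulationSummary:
    """Mean/spread of one channel for a gated condition-replicate population.

    ``sd`` uses the n-1 denominator; ``sem = sd / sqrt(n)``. A population
    of one worm reports zero spread by convention.
    """

    condition: str
    replicate: str
    channel: str
    n: int
    mean: float
    sd: float
    sem: float
    median: float
    percentiles: Mapping[float, float] = field(default_factory=dict)


def summarize_population(
    events: pd.DataFrame,
    channel: str = "green",
    percentiles: Sequence[float] = (5.0, 25.0, 50.0, 75.0, 95.0),
) -> PopulationSummary:
    """Arithmetic mean, sd (n-1) and SEM of one channel of a gated table.

    The arithmetic mean (not the median) is the headline statistic because
    the downstream index algebra works with ratios of population means;
    the median and percentile map are reported alongside.
    """
    if events is None or len(events) == 0:
        raise DataError("cannot summarize an empty event table")
    if channel not in CHANNELS:
        raise DataError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if channel not in events.columns:
        raise DataError(f"event table lacks channel column {channel!r}")
    values = events[channel].to_numpy(dtype=float)
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    sem = sd / np.sqrt(n)

    def _label(col: str) -> str:
        u = events[col].unique() if col in events.columns else []
        return str(u[0]) if len(u) == 1 else "+".join(map(str, u)) if len(u) else ""

    return PopulationSummary(
        condition=_label("condition"),
        replicate=_label("replicate"),
        channel=channel,
        n=int(n),
        mean=mean,
        sd=sd,
        sem=float(sem),
        median=float(np.median(values)),
        percentiles={float(p): float(np.percentile(values, p)) for p in percentiles},
    )


def select_percentile(
    events: pd.DataFrame, channel: str, lo_pct: float, hi_pct: float
) -> pd.DataFrame:
    """Events whose channel value lies in the [lo, hi) empirical percentile band.

    Percentile thresholds use linear interpolation; the band is closed at
    the lower threshold and open at the upper one, except that ``hi_pct =
    100`` closes the top so the maximum is selectable. Bands that partition
    [0, 100] therefore partition the table.
    """
    if not 0.0 <= lo_pct < hi_pct <= 100.0:
        raise DataError(f"need 0 <= lo < hi <= 100, got ({lo_pct}, {hi_pct})")
    if events is None or len(events) == 0:
        raise DataError("cannot select from an empty event table")
    values = events[channel].to_numpy(dtype=float)
    lo_val, hi_val = np.percentile(values, [lo_pct, hi_pct], method="linear")
    keep = values >= lo_val
    if hi_pct < 100.0:
        keep &= values < hi_val
    else:
        keep &= values <= hi_val
    return events.loc[keep].copy()


@dataclass(frozen=True)
class DeadFraction:
    """Propidium-iodide-positive proportion with a Wilson 95% interval."""

    fraction: float
    n_dead: int
    n_total: int
    ci_low: float
    ci_high: float


def dead_fraction(
    events: pd.DataFrame, red_dead_threshold: float, alpha: float = 0.05
) -> DeadFraction:
    """Fraction of gated events whose red signal exceeds the death threshold."""
    if events is None or len(events) == 0:
        raise DataError("cannot score death on an empty event table")
    red = events["red"].to_numpy(dtype=float)
    n_dead = int((red > red_dead_threshold).sum())
    n = red.size
    lo, hi = proportion_confint(n_dead, n, alpha=alpha, method="wilson")
    return DeadFraction(
        fraction=n_dead / n, n_dead=n_dead, n_total=n, ci_low=float(lo), ci_high=float(hi)
    )


def normalize_timecourse(
    summaries: Mapping[object, tuple[PopulationSummary, PopulationSummary]],
) -> pd.DataFrame:
    """Injured fluorescence normalized to age-matched uninjured controls.

    ``summaries`` maps each timepoint to an ``(injured, uninjured)`` pair
    of population summaries on the same channel. The normalized value at
    each timepoint is the ratio of means, with its uncertainty from
    quadrature propagation of the two SEMs through the quotient.
    """
    if not summaries:
        raise DataError("timecourse is empty")
    rows = []
    for t, (inj, uninj) in summaries.items():
        if inj.channel != uninj.channel:
            raise DataError(f"timepoint {t!r} mixes channels {inj.channel}/{uninj.channel}")
        value, delta = quotient_with_error(inj.mean, inj.sem, uninj.mean, uninj.sem)
        rows.append(
            {
                "timepoint": t,
                "normalized_mean": value,
                "delta": delta,
                "n_injured": inj.n,
                "n_uninjured": uninj.n,
            }
        )
    return pd.DataFrame(rows)
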