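"""Dopaminergic GFP index: screen scoring with quadrature error propagation.

The screen statistic compares the fluorescence retained after injury under
a gene knockdown to the retention under the empty-vector (EV) control:

    index = (EV - RNAi) / (EV - 1)

where EV and RNAi are each a ratio of population-mean GFP, injured over
age-matched uninjured, for that condition. An index of 1 means the
knockdown fully prevented the injury-induced loss (RNAi ratio equals the
uninjured control); 0 means the same loss as EV; negative values mean the
knockdown worsened the loss.

Uncertainties follow the quadrature rule at every step: SEM of each
population mean, through the quotient for each ratio, through the index
with EV treated as the experiment-wide constant (each contribution divided
by ``1 - EV``), and finally across biological replicates, where the
quadrature sum of per-replicate errors (scaled as an error of the mean)
combines with the between-replicate scatter of the indices.

Hits are called from normal-approximation confidence intervals: a
knockdown is protective when its interval lies entirely above zero and
sensitizing when entirely below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._propagation import quadrature, quotient_with_error
from .errors import DataError, DegenerateControlError
from .flow_gating import GateConfig, PopulationSummary, gate_events, summarize_population

__all__ = [
    "RatioWithError",
    "IndexResult",
    "ScreenHit",
    "fluorescence_ratio",
    "gfp_index",
    "combine_replicates",
    "call_hits",
    "score_screen",
    "EPSILON_GUARD",
]

#: minimum |EV - 1| below which the control shows no loss and the index is undefined
EPSILON_GUARD = 0.02


@dataclass(frozen=True)
class RatioWithError:
    """Injured/uninjured fluorescence ratio for one condition-replicate."""

    value: float
    delta: float
    n_injured: int
    n_uninjured: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DataError(f"fluorescence ratio must be > 0, got {self.value}")
        if self.delta < 0:
            raise DataError("ratio uncertainty must be >= 0")


@dataclass(frozen=True)
class IndexResult:
    """GFP index with its within/between-replicate error decomposition.

    ``delta_total**2 == delta_within**2 + delta_between**2`` and the 95%
    interval is ``index +/- 1.96 * delta_total``.
    """

    index: float
    delta_within: float
    delta_between: float
    delta_total: float
    ci_low: float
    ci_high: float
    n_replicates: int


@dataclass(frozen=True)
class ScreenHit:
    gene: str
    result: IndexResult
    classification: str  # protective | sensitizing | no_effect


def fluorescence_ratio(
    injured: PopulationSummary, uninjured: PopulationSummary
) -> RatioWithError:
    """Ratio of injured to uninjured population-mean fluorescence.

    The uncertainty applies the quadrature rule to the quotient of two
    independent means: ``delta = R * sqrt((sem_i/m_i)^2 + (sem_u/m_u)^2)``.
    """
    if injured.channel != uninjured.channel:
        raise DataError(
            f"ratio mixes channels {injured.channel!r} and {uninjured.channel!r}"
        )
    value, delta = quotient_with_error(injured.mean, injured.sem, uninjured.mean, uninjured.sem)
    return RatioWithError(
        value=value, delta=delta, n_injured=injured.n, n_uninjured=uninjured.n
    )


def gfp_index(
    ev: RatioWithError,
    rnai: RatioWithError,
    epsilon_guard: float = EPSILON_GUARD,
    z: float = 1.96,
) -> IndexResult:
    """Single-replicate GFP index with propagated uncertainty.

    ``index = (ev - rnai) / (ev - 1)``. The EV ratio is treated as the
    experiment-wide constant of the error formula, so each uncertainty
    enters as ``delta_X / (1 - EV)`` and the two contributions add in
    quadrature. Controls with ``|ev - 1| <= epsilon_guard`` are rejected:
    if injury removed no fluorescence in the EV arm there is nothing to
    normalize against.
    """
    if abs(ev.value - 1.0) <= epsilon_guard:
        raise DegenerateControlError(
            f"EV ratio {ev.value:.4f} is within {epsilon_guard} of 1: "
            "no fluorescence loss in the control, index undefined"
        )
    denom = ev.value - 1.0
    index = (ev.value - rnai.value) / denom
    delta_within = quadrature(ev.delta / abs(denom), rnai.delta / abs(denom))
    return IndexResult(
        index=index,
        delta_within=delta_within,
        delta_between=0.0,
        delta_total=delta_within,
        ci_low=index - z * delta_within,
        ci_high=index + z * delta_within,
        n_replicates=1,
    )


def combine_replicates(per_replicate: Sequence[IndexResult], z: float = 1.96) -> IndexResult:
    """Average replicate indices, combining error sources in quadrature.

    The within-replicate errors combine as the error of a mean
    (``sqrt(sum delta_r^2) / n``); the between-replicate term is the SEM of
    the replicate indices; the two add in quadrature to the total.
    """
    if len(per_replicate) == 0:
        raise DataError("need at least one replicate to combine")
    n = len(per_replicate)
    indices = np.array([r.index for r in per_replicate])
    index = float(indices.mean())
    delta_within = math.sqrt(sum(r.delta_total**2 for r in per_replicate)) / n
    delta_between = float(indices.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    delta_total = quadrature(delta_within, delta_between)
    return IndexResult(
        index=index,
        delta_within=delta_within,
        delta_between=delta_between,
        delta_total=delta_total,
        ci_low=index - z * delta_total,
        ci_high=index + z * delta_total,
        n_replicates=n,
    )


def _classify(result: IndexResult, z: float) -> str:
    lo = result.index - z * result.delta_total
    hi = result.index + z * result.delta_total
    if lo > 0:
        return "protective"
    if hi < 0:
        return "sensitizing"
    return "no_effect"


def call_hits(
    results: Mapping[str, IndexResult], alpha: float = 0.05
) -> list[ScreenHit]:
    """Classify each knockdown from its confidence interval.

    Protective when the (1 - alpha) interval lies above zero, sensitizing
    when below, otherwise no effect. Output is sorted by index,
    descending (most protective first).
    """
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    hits = [
        ScreenHit(gene=g, result=r, classification=_classify(r, z))
        for g, r in results.items()
    ]
    return sorted(hits, key=lambda h: h.result.index, reverse=True)


def score_screen(
    experiment: Mapping[str, Sequence[tuple[pd.DataFrame, pd.DataFrame]]],
    gates: GateConfig | None = None,
    channel: str = "green",
    alpha: float = 0.05,
    epsilon_guard: float = EPSILON_GUARD,
) -> tuple[list[ScreenHit], pd.DataFrame]:
    """Full screen pipeline: gate, summarize, ratio, index, combine, call.

    ``experiment`` maps each RNAi gene (the "EV" control must be present)
    to one ``(injured, uninjured)`` event-table pair per replicate. When no
    gates are supplied they are derived from the first uninjured EV table.
    Returns the called hits and a per-gene report table.
    """
    if "EV" not in experiment:
        raise DataError('the screen requires an "EV" control condition')
    n_reps = len(experiment["EV"])
    if any(len(pairs) != n_reps for pairs in experiment.values()):
        raise DataError("all genes must have the same number of replicates")
    if gates is None:
        gates = GateConfig.from_reference(experiment["EV"][0][1])

    def _ratio(pair: tuple[pd.DataFrame, pd.DataFrame]) -> RatioWithError:
        injured, _ = gate_events(pair[0], gates)
        uninjured, _ = gate_events(pair[1], gates)
        return fluorescence_ratio(
            summarize_population(injured, channel), summarize_population(uninjured, channel)
        )

    ev_ratios = [_ratio(pair) for pair in experiment["EV"]]
    results: dict[str, IndexResult] = {}
    for gene, pairs in experiment.items():
        per_rep = []
        for r, pair in enumerate(pairs):
            rnai_ratio = ev_ratios[r] if gene == "EV" else _ratio(pair)
            per_rep.append(gfp_index(ev_ratios[r], rnai_ratio, epsilon_guard=epsilon_guard))
        results[gene] = combine_replicates(per_rep)

    hits = call_hits(results, alpha=alpha)
    report = pd.DataFrame(
        [
            {
                "gene": h.gene,
                "index": h.result.index,
                "delta_within": h.result.delta_within,
                "delta_between": h.result.delta_between,
                "delta_total": h.result.delta_total,
                "ci_low": h.result.ci_low,
                "ci_high": h.result.ci_high,
                "n_replicates": h.result.n_replicates,
                "classification": h.classification,
            }
            for h in hits
        ]
    )
    return hits, report
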