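"""Exactly-specified small-assay computations.

Chemotaxis quadrant index, paralysis fractions with Wilson intervals,
per-worm nose-touch scoring, movement-phenotype tallies, and delta-Ct
qPCR quantification with melt-curve exclusion and two-housekeeping-gene
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError

__all__ = [
    "QuadrantCounts",
    "HOUSEKEEPING_GENES",
    "chemotactic_index",
    "paralysis_fraction",
    "nose_touch_score",
    "movement_phenotype_tally",
    "qpcr_relative_abundance",
]

#: default housekeeping transcripts for qPCR normalization
HOUSEKEEPING_GENES = ("tba-1", "Y45F10D.4")

#: closed category set for movement scoring after trauma
MOVEMENT_CATEGORIES = (
    "normal",
    "increased_amplitude",
    "decreased_amplitude",
    "increased_curvature",
    "erratic",
    "no_movement",
)


@dataclass(frozen=True)
class QuadrantCounts:
    """Worm counts from a four-quadrant chemotaxis plate.

    Worms in the neutral center circle count toward ``n_total`` but toward
    neither attractant tally (the index denominator is the total number of
    scored worms).
    """

    n_butanol: int
    n_ethanol: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise DataError("n_total must be >= 1")
        if min(self.n_butanol, self.n_ethanol) < 0:
            raise DataError("quadrant counts must be >= 0")
        if self.n_butanol + self.n_ethanol > self.n_total:
            raise DataError("quadrant counts exceed the total scored")


def chemotactic_index(counts: QuadrantCounts) -> float:
    """(#butanol - #ethanol) / #total, in [-1, 1].

    1.0 means every worm chose the attractant quadrants, 0.0 no
    preference, negative values avoidance.
    """
    return (counts.n_butanol - counts.n_ethanol) / counts.n_total


def paralysis_fraction(
    n_paralyzed: int, n_scored: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Paralyzed proportion with its Wilson (1 - alpha) interval."""
    if n_scored < 1:
        raise DataError("n_scored must be >= 1")
    if not 0 <= n_paralyzed <= n_scored:
        raise DataError("n_paralyzed must lie in [0, n_scored]")
    lo, hi = proportion_confint(n_paralyzed, n_scored, alpha=alpha, method="wilson")
    return n_paralyzed / n_scored, (float(lo), float(hi))


def nose_touch_score(
    trials: Sequence[Sequence[bool]], n_trials: int = 5
) -> tuple[np.ndarray, float, float]:
    """Per-worm percent positive nose-touch responses, plus mean +/- SEM.

    The worm, not the individual touch, is the unit of analysis: each worm
    contributes one percent-positive value (out of ``n_trials`` touches)
    and the population mean and SEM are taken over worms.
    """
    if len(trials) == 0:
        raise DataError("no worms scored")
    bad = [i for i, t in enumerate(trials) if len(t) != n_trials]
    if bad:
        raise DataError(f"worms with trial count != {n_trials}: {bad[:5]}")
    per_worm = np.array([100.0 * sum(map(bool, t)) / n_trials for t in trials])
    mean = float(per_worm.mean())
    sem = float(per_worm.std(ddof=1) / np.sqrt(per_worm.size)) if per_worm.size > 1 else 0.0
    return per_worm, mean, sem


def movement_phenotype_tally(
    labels: Iterable[str], categories: Sequence[str] = MOVEMENT_CATEGORIES
) -> pd.DataFrame:
    """Frequency table of movement phenotypes with proportions summing to 1."""
    labels = list(labels)
    if not labels:
        raise DataError("no worms scored for movement")
    unknown = sorted(set(labels) - set(categories))
    if unknown:
        raise DataError(f"labels outside the declared category set: {unknown}")
    counts = pd.Series(labels).value_counts()
    table = pd.DataFrame(
        {
            "category": list(categories),
            "count": [int(counts.get(c, 0)) for c in categories],
        }
    )
    table["proportion"] = table["count"] / len(labels)
    return table


def qpcr_relative_abundance(
    ct: pd.DataFrame,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
    reference_sample: str | None = None,
) -> pd.DataFrame:
    """Delta-Ct quantification with geometric-mean housekeeping normalization.

    Technical replicates with more than one melt-curve peak are excluded
    (off-target amplification); remaining replicates are averaged per
    (sample, gene). The delta Ct of a target is its mean Ct minus the
    arithmetic mean of the two housekeeping mean Cts -- algebraically
    identical to dividing the target's ``2**-Ct`` level by the geometric
    mean of the two housekeeping levels -- and the relative level is
    ``2**-deltaCt`` (100% amplification efficiency assumed). When
    ``reference_sample`` is given, each gene's levels are further divided
    by that sample's level (fold change versus the reference condition).

    ``ct`` needs columns sample, gene, technical_rep, ct, melt_peaks.
    """
    required = {"sample", "gene", "technical_rep", "ct", "melt_peaks"}
    missing = required - set(ct.columns)
    if missing:
        raise DataError(f"Ct table lacks columns: {sorted(missing)}")
    if len(housekeeping) != 2:
        raise DataError("exactly two housekeeping genes are required")
    if (ct["ct"] <= 0).any():
        raise DataError("Ct values must be > 0 cycles")

    kept = ct[ct["melt_peaks"] <= 1]
    lost = set(map(tuple, ct[["sample", "gene"]].drop_duplicates().to_numpy())) - set(
        map(tuple, kept[["sample", "gene"]].drop_duplicates().to_numpy())
    )
    if lost:
        raise DataError(
            f"all technical replicates excluded by melt-curve analysis for: {sorted(lost)}"
        )
    mean_ct = kept.groupby(["sample", "gene"])["ct"].mean()

    rows = []
    for sample in kept["sample"].unique():
        sample_ct = mean_ct.loc[sample]
        hk_missing = [h for h in housekeeping if h not in sample_ct.index]
        if hk_missing:
            raise DataError(f"sample {sample!r} lacks housekeeping genes {hk_missing}")
        hk_mean = float(np.mean([sample_ct[h] for h in housekeeping]))
        for gene, gene_ct in sample_ct.items():
            if gene in housekeeping:
                continue
            delta_ct = float(gene_ct) - hk_mean
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "mean_ct": float(gene_ct),
                    "delta_ct": delta_ct,
                    "relative_level": 2.0**-delta_ct,
                }
            )
    result = pd.DataFrame(rows)
    if reference_sample is not None:
        if reference_sample not in set(result["sample"]):
            raise DataError(f"reference sample {reference_sample!r} not in the table")
        ref = result[result["sample"] == reference_sample].set_index("gene")["relative_level"]
        result["fold_change"] = [
            row.relative_level / ref[row.gene] if row.gene in ref.index else np.nan
            for row in result.itertuples()
        ]
    return result
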