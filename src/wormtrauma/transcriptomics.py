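"""Differential expression filtering, cross-correlation of stress
signatures, set overlaps, and candidate selection.

The trauma transcriptome work rests on a handful of well-defined
operations rather than any novel statistic: per-gene two-group tests with
fold-change and significance thresholds (raw p for array-style data,
Benjamini-Hochberg FDR for sequencing-style data), z-normalized Pearson
cross-correlation of fold-change vectors across published stress datasets
with complete-case NaN handling, exact set algebra for response overlaps,
a paired day-1 versus day-4 attenuation comparison, and the funnel that
filters significant genes down to screenable RNAi candidates.

Fold-change vectors are correlated on the log2 scale by default (effects
are multiplicative, and log fold changes are what the latent-program
structure acts on); the input is assumed already log2 unless stated
otherwise via ``data_kind``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "CorrelationMatrix",
    "benjamini_hochberg",
    "differential_expression",
    "zscore_normalize",
    "cross_correlate",
    "overlap_sets",
    "age_response_trend",
    "screen_candidate_filter",
]


def benjamini_hochberg(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a vector of p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def differential_expression(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr: bool = False,
    data_kind: str = "linear",
) -> pd.DataFrame:
    """Per-gene Welch t-test with fold-change and significance thresholds.

    Testing runs on log2-transformed values (Welch, two-sided); the fold
    change is the ratio of group means on the linear scale (group A over
    group B). A gene is significant when ``|FC| >= fc_threshold`` (i.e.
    ``|log2 FC| >= log2(fc_threshold)``, inclusive at the boundary) and the
    raw p-value -- or its Benjamini-Hochberg q-value when ``fdr=True`` --
    is at most ``p_threshold``. Genes with zero variance in both groups
    get ``p = 1`` by convention.

    Parameters
    ----------
    expr : genes x samples matrix; strictly positive when ``data_kind ==
        "linear"``, already log2 when ``data_kind == "log2"``.
    """
    if data_kind not in ("linear", "log2"):
        raise DataError(f"data_kind must be 'linear' or 'log2', got {data_kind!r}")
    for name, cols in (("group_a", group_a), ("group_b", group_b)):
        if len(cols) < 2:
            raise DataError(f"{name} needs >= 2 samples, got {len(cols)}")
        missing = [c for c in cols if c not in expr.columns]
        if missing:
            raise DataError(f"{name} columns not in matrix: {missing}")

    a = expr[list(group_a)].to_numpy(dtype=float)
    b = expr[list(group_b)].to_numpy(dtype=float)
    if data_kind == "linear":
        if (a <= 0).any() or (b <= 0).any():
            raise DataError("linear expression values must be > 0 for fold-change")
        log_a, log_b = np.log2(a), np.log2(b)
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    else:
        log_a, log_b = a, b
        mean_a, mean_b = np.exp2(a).mean(axis=1), np.exp2(b).mean(axis=1)

    log2fc = np.log2(mean_a / mean_b)
    t_res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    flat = (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0)
    p[flat & (np.abs(log_a.mean(axis=1) - log_b.mean(axis=1)) == 0)] = 1.0
    p[np.isnan(p)] = 1.0

    q = benjamini_hochberg(p)
    crit = q if fdr else p
    significant = (np.abs(log2fc) >= np.log2(fc_threshold)) & (crit <= p_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": significant,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=expr.index,
    )


def zscore_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Center and scale to unit sd (n-1), preserving NaN positions."""
    arr = np.asarray(values, dtype=float)
    finite = ~np.isnan(arr)
    if finite.sum() < 2:
        raise DataError("need >= 2 non-NaN values to z-normalize")
    sd = arr[finite].std(ddof=1)
    if sd == 0:
        raise DataError("cannot z-normalize a constant vector (zero sd)")
    out = arr.copy()
    out[finite] = (arr[finite] - arr[finite].mean()) / sd
    return out


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson cross-correlation of dataset fold-change vectors."""

    labels: tuple[str, ...]
    r: pd.DataFrame
    n_genes_used: int


def cross_correlate(
    datasets: pd.DataFrame | Mapping[str, pd.Series],
    reference_set: Iterable[str],
    nan_policy: str = "complete",
) -> CorrelationMatrix:
    """Pearson correlation matrix of fold-change vectors over a gene set.

    The procedure mirrors signature-comparison practice: restrict every
    dataset to the reference gene set (the genes significantly regulated in
    the anchor experiment), z-normalize each dataset, drop every gene that
    is NaN in *any* dataset (``nan_policy="complete"``, matching a
    concatenate-then-filter workflow; ``"pairwise"`` keeps per-pair
    complete cases instead), and correlate the aligned remainder.
    """
    if isinstance(datasets, Mapping):
        datasets = pd.DataFrame(datasets)
    if datasets.shape[1] < 2:
        raise DataError("need >= 2 datasets to cross-correlate")
    if nan_policy not in ("complete", "pairwise"):
        raise DataError(f"nan_policy must be 'complete' or 'pairwise', got {nan_policy!r}")
    reference = [g for g in reference_set]
    if not reference:
        raise DataError("reference gene set is empty")
    missing = [g for g in reference if g not in datasets.index]
    if missing:
        raise DataError(f"reference genes absent from the matrix: {missing[:5]}")
    sub = datasets.loc[reference]

    normed = pd.DataFrame(
        {c: zscore_normalize(sub[c].to_numpy()) for c in sub.columns}, index=sub.index
    )

    labels = tuple(map(str, sub.columns))
    if nan_policy == "complete":
        complete = normed.dropna(axis=0, how="any")
        if len(complete) < 3:
            raise DataError(
                f"only {len(complete)} complete-case genes; >= 3 required for correlation"
            )
        r = np.corrcoef(complete.to_numpy(dtype=float), rowvar=False)
        r_df = pd.DataFrame(r, index=labels, columns=labels)
        n_used = len(complete)
    else:
        r_df = normed.corr(method="pearson", min_periods=3)
        r_df.index = r_df.columns = labels
        if r_df.isna().any().any():
            raise DataError("a dataset pair has < 3 jointly observed genes")
        n_used = int(normed.notna().all(axis=1).sum())
    return CorrelationMatrix(labels=labels, r=r_df, n_genes_used=n_used)


def overlap_sets(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Exact two-set overlap: counts plus sorted membership lists."""
    a, b = set(set_a), set(set_b)
    shared = a & b
    return {
        "a_only": len(a - b),
        "shared": len(shared),
        "b_only": len(b - a),
        "a_only_genes": sorted(a - b),
        "shared_genes": sorted(shared),
        "b_only_genes": sorted(b - a),
    }


def age_response_trend(
    fc_day1: pd.Series | np.ndarray,
    fc_day4: pd.Series | np.ndarray,
    fc_threshold: float = 2.0,
    data_kind: str = "linear",
) -> dict:
    """Paired comparison of stress-gene induction at two ages.

    Both vectors list the fold change of the same stress-activated genes
    (same order), each normalized to age-matched uninjured controls. The
    comparison runs on log2 values: reported are the mean day1 - day4
    difference, a two-sided paired t-test p-value, and how many genes stay
    above the fold-change threshold at both ages. Identical vectors give a
    mean difference of 0 and p = 1 by convention.
    """
    d1 = np.asarray(fc_day1, dtype=float)
    d4 = np.asarray(fc_day4, dtype=float)
    if d1.shape != d4.shape:
        raise DataError("day-1 and day-4 vectors must have the same gene order/length")
    if d1.size < 3:
        raise DataError("need >= 3 genes for the paired trend")
    if data_kind == "linear":
        if (d1 <= 0).any() or (d4 <= 0).any():
            raise DataError("linear fold changes must be > 0")
        l1, l4 = np.log2(d1), np.log2(d4)
    elif data_kind == "log2":
        l1, l4 = d1, d4
    else:
        raise DataError(f"data_kind must be 'linear' or 'log2', got {data_kind!r}")
    diff = l1 - l4
    if np.allclose(diff, diff[0]) and diff[0] == 0:
        p = 1.0
    else:
        p = float(stats.ttest_rel(l1, l4).pvalue)
        if np.isnan(p):
            p = 1.0
    thr = np.log2(fc_threshold)
    return {
        "n_genes": int(d1.size),
        "mean_log2_day1": float(l1.mean()),
        "mean_log2_day4": float(l4.mean()),
        "mean_diff": float(diff.mean()),
        "p": p,
        "n_above_threshold_both": int(((l1 >= thr) & (l4 >= thr)).sum()),
    }


def screen_candidate_filter(
    de: pd.DataFrame,
    annotations: pd.DataFrame,
    expression_threshold: float = 1.0,
    require_rnai: bool = True,
) -> list[str]:
    """Funnel significant genes down to screenable RNAi candidates.

    A gene passes when it is significant in ``de`` and its annotation row
    shows transcript abundance above ``expression_threshold``, expression
    in the nervous system, a mammalian homolog, and (when ``require_rnai``)
    an available RNAi clone. Genes missing from the annotation table are
    treated as failing every flag. Order of ``de.index`` is preserved.
    """
    if "significant" not in de.columns:
        raise DataError("de table lacks a 'significant' column")
    candidates = []
    for gene in de.index[de["significant"].to_numpy(dtype=bool)]:
        if gene not in annotations.index:
            continue
        row = annotations.loc[gene]
        ok = (
            float(row.get("expression_level", 0.0)) > expression_threshold
            and bool(row.get("neuronal", False))
            and bool(row.get("homolog", False))
        )
        if require_rnai:
            ok = ok and bool(row.get("rnai_available", False))
        if ok:
            candidates.append(gene)
    return candidates
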