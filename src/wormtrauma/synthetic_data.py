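"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: COPAS-style
per-object event tables (time-of-flight, extinction, green and red
fluorescence), whole RNAi-screen experiments with a planted per-gene
protection index, gene-by-dataset fold-change matrices with latent stress
programs driving known cross-dataset correlations, and small behavioral /
qPCR count tables. Each generator returns the data together with a
:class:`GroundTruth` record so downstream stages can be tested by parameter
recovery rather than against deposited animal data.

Optical channels are modeled as lognormals: large-particle cytometry
intensities are strictly positive and right-skewed, and a multiplicative
injury effect acts naturally on the log scale. Contaminant subpopulations
(larvae, bacteria, doublets, curled worms) are parameterized relative to
the adult distributions so gates derived from adult medians separate them
without magic numbers.

Injury is a two-component mixture: a Bernoulli-chosen "affected" fraction
of worms loses GFP by a multiplicative factor while the rest retain their
healthy signal, reflecting the per-animal heterogeneity seen after blunt
trauma (some animals keep intact dopaminergic neurons).

A single integer seed governs a hierarchical stream keyed by
(gene, replicate, arm), so adding conditions to an experiment never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "FlowSimConfig",
    "ScreenSimConfig",
    "ExprSimConfig",
    "GroundTruth",
    "generate_flow_events",
    "generate_screen_experiment",
    "generate_stress_expression",
    "generate_quadrant_counts",
    "generate_paralysis_counts",
    "generate_nose_touch_trials",
    "generate_ct_table",
    "planted_injury_factor",
]

EVENT_COLUMNS = ("event_id", "tof", "extinction", "green", "red", "condition", "replicate")

#: classes an event can truly belong to, in the order contaminant draws use
EVENT_CLASSES = ("adult", "larva", "bacteria", "doublet", "curl")


@dataclass
class GroundTruth:
    """Planted simulation parameters emitted alongside generated data.

    Only the fields relevant to the generator that produced it are filled.
    """

    #: per event: true class, injury-affected flag, dead flag
    event_truth: pd.DataFrame | None = None
    #: per gene: the planted protection index (expectation of the recovered one)
    true_index: dict[str, float] | None = None
    #: per (gene, replicate): index after day-to-day jitter, and GFP factor used
    replicate_index: pd.DataFrame | None = None
    #: dataset-by-dataset Pearson correlation implied by the linear model
    true_correlation: pd.DataFrame | None = None
    #: genes carrying a planted differential-expression effect
    de_genes: list[str] | None = None
    #: free-form record of the generating parameters
    params: dict | None = None


# ---------------------------------------------------------------------------
# flow events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowSimConfig:
    """Parameters for one condition/replicate worth of COPAS events.

    ``*_mu``/``*_sigma`` are natural-log parameters of lognormal channels
    (so ``exp(mu)`` is the channel median in instrument units).
    Contaminant channel scales are multiples of the adult medians.
    """

    n_worms: int = 500
    condition: str = "uninjured"
    replicate: str = "rep1"
    # adult optics
    adult_tof_mu: float = math.log(400.0)
    adult_tof_sigma: float = 0.25
    adult_ext_mu: float = math.log(300.0)
    adult_ext_sigma: float = 0.25
    gfp_mu: float = math.log(200.0)
    gfp_sigma: float = 0.5
    # red channel (propidium iodide): alive worms sit low, dead worms high
    red_alive_mu: float = math.log(5.0)
    red_dead_mu: float = math.log(500.0)
    red_sigma: float = 0.4
    # injury model: a Bernoulli fraction of worms loses GFP multiplicatively
    injured: bool = False
    injury_affected_fraction: float = 0.7
    injury_gfp_factor: float = 0.4
    # contaminants, as fractions of all detected objects
    contaminant_fractions: Mapping[str, float] = field(default_factory=dict)
    red_death_fraction: float = 0.0
    # contaminant optics relative to adult medians
    larva_scale: float = 0.25
    bacteria_scale: float = 0.02
    curl_tof_scale: float = 0.55
    curl_ext_scale: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms <= 0:
            raise ConfigurationError(f"n_worms must be positive, got {self.n_worms}")
        for name in ("adult_tof_sigma", "adult_ext_sigma", "gfp_sigma", "red_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("injury_affected_fraction", "red_death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.injury_gfp_factor <= 1.0:
            raise ConfigurationError(
                f"injury_gfp_factor must lie in (0, 1], got {self.injury_gfp_factor}"
            )
        bad = set(self.contaminant_fractions) - {"larva", "bacteria", "doublet", "curl"}
        if bad:
            raise ConfigurationError(f"unknown contaminant classes: {sorted(bad)}")
        fracs = list(self.contaminant_fractions.values())
        if any(not 0.0 <= f < 1.0 for f in fracs):
            raise ConfigurationError("contaminant fractions must lie in [0, 1)")
        if sum(fracs) >= 1.0:
            raise ConfigurationError("contaminant fractions must sum to < 1")


def _lognormal(rng: np.random.Generator, mu: float, sigma: float, n: int) -> np.ndarray:
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def generate_flow_events(
    config: FlowSimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one table of COPAS events for a single condition/replicate.

    Adults draw all channels from the configured lognormals. Larvae scale
    TOF/extinction (and GFP) down by ``larva_scale``; bacterial debris sits
    near zero on every channel; doublets are the channel-wise sum of two
    adult draws; curled worms present short TOF but high extinction.
    In injured conditions a Bernoulli(``injury_affected_fraction``) subset
    of worm-class events has its GFP multiplied by ``injury_gfp_factor``.
    A ``red_death_fraction`` subset of adults draws red fluorescence from
    the separated "dead" distribution.

    Deterministic given ``(config, seed)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_worms
    frac = dict(config.contaminant_fractions)
    probs = np.array(
        [
            1.0 - sum(frac.values()),
            frac.get("larva", 0.0),
            frac.get("bacteria", 0.0),
            frac.get("doublet", 0.0),
            frac.get("curl", 0.0),
        ]
    )
    classes = rng.choice(len(EVENT_CLASSES), size=n, p=probs)

    tof = np.empty(n)
    ext = np.empty(n)
    green = np.empty(n)

    c = config
    for ci, name in enumerate(EVENT_CLASSES):
        idx = np.flatnonzero(classes == ci)
        m = idx.size
        if m == 0:
            continue
        if name == "doublet":
            tof[idx] = _lognormal(rng, c.adult_tof_mu, c.adult_tof_sigma, m) + _lognormal(
                rng, c.adult_tof_mu, c.adult_tof_sigma, m
            )
            ext[idx] = _lognormal(rng, c.adult_ext_mu, c.adult_ext_sigma, m) + _lognormal(
                rng, c.adult_ext_mu, c.adult_ext_sigma, m
            )
            green[idx] = _lognormal(rng, c.gfp_mu, c.gfp_sigma, m) + _lognormal(
                rng, c.gfp_mu, c.gfp_sigma, m
            )
            continue
        t_scale = e_scale = g_scale = 1.0
        if name == "larva":
            t_scale = e_scale = g_scale = c.larva_scale
        elif name == "bacteria":
            t_scale = e_scale = g_scale = c.bacteria_scale
        elif name == "curl":
            t_scale, e_scale = c.curl_tof_scale, c.curl_ext_scale
        tof[idx] = t_scale * _lognormal(rng, c.adult_tof_mu, c.adult_tof_sigma, m)
        ext[idx] = e_scale * _lognormal(rng, c.adult_ext_mu, c.adult_ext_sigma, m)
        green[idx] = g_scale * _lognormal(rng, c.gfp_mu, c.gfp_sigma, m)

    # injury: worm-class events (adults and curled adults) may lose GFP
    is_worm = np.isin(classes, [EVENT_CLASSES.index("adult"), EVENT_CLASSES.index("curl")])
    affected = np.zeros(n, dtype=bool)
    if c.injured and c.injury_affected_fraction > 0:
        affected = is_worm & (rng.random(n) < c.injury_affected_fraction)
        green[affected] *= c.injury_gfp_factor

    # death: a subset of adults takes up propidium iodide (high red)
    dead = np.zeros(n, dtype=bool)
    is_adult = classes == EVENT_CLASSES.index("adult")
    if c.red_death_fraction > 0:
        dead = is_adult & (rng.random(n) < c.red_death_fraction)
    red = _lognormal(rng, c.red_alive_mu, c.red_sigma, n)
    if dead.any():
        red[dead] = _lognormal(rng, c.red_dead_mu, c.red_sigma, int(dead.sum()))

    event_id = [f"{c.condition}:{c.replicate}:{i:06d}" for i in range(n)]
    events = pd.DataFrame(
        {
            "event_id": event_id,
            "tof": tof,
            "extinction": ext,
            "green": green,
            "red": red,
            "condition": c.condition,
            "replicate": c.replicate,
        }
    )
    truth = GroundTruth(
        event_truth=pd.DataFrame(
            {
                "event_id": event_id,
                "true_class": [EVENT_CLASSES[ci] for ci in classes],
                "affected": affected,
                "dead": dead,
            }
        ),
        params={
            "adult_tof_median": math.exp(c.adult_tof_mu),
            "adult_ext_median": math.exp(c.adult_ext_mu),
            "gfp_median": math.exp(c.gfp_mu),
        },
    )
    return events, truth


# ---------------------------------------------------------------------------
# screen experiments
# ---------------------------------------------------------------------------


def planted_injury_factor(true_index: float, ev_injury_gfp_factor: float) -> float:
    """GFP factor giving a population-level protection index of ``true_index``.

    Inverting the index definition ``I = (f_g - f_EV) / (1 - f_EV)`` yields
    ``f_g = 1 - (1 - I) * (1 - f_EV)``; an index of 1 means no GFP loss at
    all (factor 1), an index of 0 the same loss as the empty-vector control.
    """
    factor = 1.0 - (1.0 - true_index) * (1.0 - ev_injury_gfp_factor)
    if factor <= 0.0:
        raise ConfigurationError(
            f"true index {true_index} with EV factor {ev_injury_gfp_factor} "
            f"implies non-positive GFP factor {factor:.4f}"
        )
    return factor


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters for a full RNAi-screen simulation.

    ``true_index`` plants the expected protection index per knockdown
    (the empty-vector control "EV" must be present with index 0).
    ``replicate_index_sd`` adds Gaussian day-to-day jitter to each gene's
    per-replicate index, emulating biological variability between
    independent trials on top of per-worm sampling noise.
    """

    genes: tuple[str, ...] = ("EV",)
    true_index: Mapping[str, float] = field(default_factory=lambda: {"EV": 0.0})
    ev_injury_gfp_factor: float = 0.4
    n_replicates: int = 3
    n_worms_per_arm: int = 500
    replicate_index_sd: float = 0.08
    base: FlowSimConfig = field(default_factory=FlowSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if "EV" not in self.genes:
            raise ConfigurationError('the screen must include the "EV" control')
        if self.true_index.get("EV", 0.0) != 0.0:
            raise ConfigurationError('the planted index of "EV" must be 0 by construction')
        missing = [g for g in self.genes if g not in self.true_index]
        if missing:
            raise ConfigurationError(f"genes without a planted index: {missing}")
        if not 0.0 < self.ev_injury_gfp_factor < 1.0:
            raise ConfigurationError("ev_injury_gfp_factor must lie in (0, 1)")
        if self.n_replicates < 1 or self.n_worms_per_arm < 1:
            raise ConfigurationError("n_replicates and n_worms_per_arm must be >= 1")
        if self.replicate_index_sd < 0:
            raise ConfigurationError("replicate_index_sd must be >= 0")
        for g in self.genes:
            planted_injury_factor(self.true_index[g], self.ev_injury_gfp_factor)


def generate_screen_experiment(
    config: ScreenSimConfig,
) -> tuple[dict[str, list[tuple[pd.DataFrame, pd.DataFrame]]], GroundTruth]:
    """Simulate injured/uninjured event-table pairs for every screen gene.

    Returns a mapping ``gene -> [(injured, uninjured), ...]`` (one pair per
    replicate) plus ground truth carrying the planted and per-replicate
    indices. Random streams are keyed by (gene position, replicate, arm),
    so extending the gene list leaves earlier draws untouched.
    """
    experiment: dict[str, list[tuple[pd.DataFrame, pd.DataFrame]]] = {}
    truth_rows = []
    c = config
    for gi, gene in enumerate(c.genes):
        pairs = []
        for r in range(c.n_replicates):
            rep = f"rep{r + 1}"
            # day-to-day jitter on the replicate's true index (EV anchors 0)
            if gene == "EV" or c.replicate_index_sd == 0:
                rep_index = c.true_index[gene]
            else:
                jit = np.random.default_rng(
                    np.random.SeedSequence((c.seed, gi, r, 3))
                ).normal(0.0, c.replicate_index_sd)
                rep_index = c.true_index[gene] + jit
            # same inversion as planted_injury_factor, but day-to-day jitter is
            # truncated so the factor stays a physical multiplier in (0, 1]
            factor = 1.0 - (1.0 - rep_index) * (1.0 - c.ev_injury_gfp_factor)
            factor = float(np.clip(factor, 0.02, 1.0))
            arm_tables = []
            for arm, injured in ((0, True), (1, False)):
                arm_cfg = replace(
                    c.base,
                    n_worms=c.n_worms_per_arm,
                    condition=gene,
                    replicate=rep,
                    injured=injured,
                    injury_gfp_factor=factor if injured else c.base.injury_gfp_factor,
                )
                rng = np.random.default_rng(np.random.SeedSequence((c.seed, gi, r, arm)))
                events, _ = generate_flow_events(arm_cfg, rng=rng)
                arm_tables.append(events)
            pairs.append((arm_tables[0], arm_tables[1]))
            truth_rows.append(
                {"gene": gene, "replicate": rep, "rep_index": rep_index, "gfp_factor": factor}
            )
        experiment[gene] = pairs
    truth = GroundTruth(
        true_index=dict(c.true_index),
        replicate_index=pd.DataFrame(truth_rows),
        params={"ev_injury_gfp_factor": c.ev_injury_gfp_factor},
    )
    return experiment, truth


# ---------------------------------------------------------------------------
# stress-transcriptome fold-change matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExprSimConfig:
    """Latent-program model for cross-dataset fold-change vectors.

    Each dataset's per-gene log2 fold change is a weighted sum of latent
    stress "programs" (shared transcriptional modules) plus Gaussian noise:
    ``x[d, g] = sum_p loading[d, p] * effect[p, g] + N(0, noise_sd^2)``.
    Correlations between datasets over the gene ensemble follow in closed
    form from the loadings, the program-effect covariance, and the noise.
    """

    n_genes: int = 2000
    loading_matrix: tuple[tuple[float, ...], ...] = ((1.0,), (1.0,))
    program_effect_sd: float = 1.0
    program_gene_effects: tuple[tuple[float, ...], ...] | None = None
    noise_sd: float = 0.2
    nan_fraction: float = 0.0
    dataset_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ConfigurationError("n_genes must be >= 3")
        n_prog = {len(row) for row in self.loading_matrix}
        if len(n_prog) != 1:
            raise ConfigurationError("loading_matrix rows must have equal length")
        if self.program_gene_effects is not None:
            if len(self.program_gene_effects) != next(iter(n_prog)):
                raise ConfigurationError(
                    "program_gene_effects must have one row per latent program"
                )
            if any(len(row) != self.n_genes for row in self.program_gene_effects):
                raise ConfigurationError("program_gene_effects rows must span n_genes")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.nan_fraction < 1.0:
            raise ConfigurationError("nan_fraction must lie in [0, 1)")
        if self.dataset_labels is not None and len(self.dataset_labels) != len(
            self.loading_matrix
        ):
            raise ConfigurationError("dataset_labels must match loading_matrix rows")
        if self.program_effect_sd <= 0:
            raise ConfigurationError("program_effect_sd must be > 0")


def generate_stress_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate gene-by-dataset log2 fold-change vectors with known correlation.

    Returns a genes x datasets :class:`~pandas.DataFrame` (NaN-injected when
    requested) and ground truth holding the dataset correlation matrix
    implied by the linear model. For ``noise_sd = 0`` the empirical Pearson
    correlation of the generated matrix equals the closed form exactly.
    """
    c = config
    rng = np.random.default_rng(np.random.SeedSequence(c.seed))
    L = np.asarray(c.loading_matrix, dtype=float)  # datasets x programs
    n_datasets, n_programs = L.shape
    if c.program_gene_effects is not None:
        E = np.asarray(c.program_gene_effects, dtype=float)
    else:
        E = rng.normal(0.0, c.program_effect_sd, size=(n_programs, c.n_genes))
    X = L @ E  # datasets x genes
    if c.noise_sd > 0:
        X = X + rng.normal(0.0, c.noise_sd, size=X.shape)

    labels = (
        list(c.dataset_labels)
        if c.dataset_labels is not None
        else [f"dataset_{d + 1}" for d in range(n_datasets)]
    )
    genes = [f"gene_{g + 1:05d}" for g in range(c.n_genes)]
    matrix = pd.DataFrame(X.T, index=pd.Index(genes, name="gene_id"), columns=labels)

    # closed-form correlation over the gene ensemble: Sigma = L C_E L' + s^2 I,
    # with C_E the empirical (n-1) covariance of the program effect vectors
    if c.n_genes > 1:
        C_E = np.atleast_2d(np.cov(E, ddof=1))
    else:  # pragma: no cover - guarded by config validation
        C_E = np.zeros((n_programs, n_programs))
    sigma = L @ C_E @ L.T + (c.noise_sd**2) * np.eye(n_datasets)
    d = np.sqrt(np.diag(sigma))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sigma / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    true_corr = pd.DataFrame(r, index=labels, columns=labels)

    if c.nan_fraction > 0:
        mask = rng.random(matrix.shape) < c.nan_fraction
        matrix = matrix.mask(mask)

    truth = GroundTruth(true_correlation=true_corr, params={"noise_sd": c.noise_sd})
    return matrix, truth


# ---------------------------------------------------------------------------
# small assay tables
# ---------------------------------------------------------------------------


def generate_quadrant_counts(
    p_butanol: float, p_ethanol: float, n_total: int, seed: int = 0
):
    """Multinomial quadrant assay: each worm ends in a butanol quadrant, an
    ethanol quadrant, or the neutral center with the stated probabilities."""
    from .assay_metrics import QuadrantCounts

    for name, p in (("p_butanol", p_butanol), ("p_ethanol", p_ethanol)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    if p_butanol + p_ethanol > 1.0:
        raise ConfigurationError("p_butanol + p_ethanol must not exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_b, n_e, _ = rng.multinomial(
        n_total, [p_butanol, p_ethanol, 1.0 - p_butanol - p_ethanol]
    )
    return QuadrantCounts(n_butanol=int(n_b), n_ethanol=int(n_e), n_total=int(n_total))


def generate_paralysis_counts(p_paralyzed: float, n_scored: int, seed: int = 0) -> tuple[int, int]:
    """Binomial paralysis tally ``(n_paralyzed, n_scored)``."""
    if not 0.0 <= p_paralyzed <= 1.0:
        raise ConfigurationError("p_paralyzed must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return int(rng.binomial(n_scored, p_paralyzed)), int(n_scored)


def generate_nose_touch_trials(
    p_response: float, n_worms: int, n_trials: int = 5, seed: int = 0
) -> list[list[bool]]:
    """Per-worm Bernoulli nose-touch responses (``n_trials`` touches each)."""
    if not 0.0 <= p_response <= 1.0:
        raise ConfigurationError("p_response must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.random((n_worms, n_trials)) < p_response
    return [list(map(bool, row)) for row in draws]


def generate_ct_table(
    relative_levels: Mapping[tuple[str, str], float],
    housekeeping: Sequence[str] = ("tba-1", "Y45F10D.4"),
    hk_baseline: float = 18.0,
    noise_sd: float = 0.05,
    n_reps: int = 3,
    melt_flag_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with technical replicates and melt flags.

    Target Ct values follow ``Ct = hk_baseline - log2(level) + noise`` so
    that the delta-Ct quantification recovers ``level`` relative to the
    housekeeping baseline; both housekeeping genes sit at the baseline.
    A ``melt_flag_fraction`` of technical replicates is marked with two
    melt-curve peaks (failed amplification specificity) and, to make the
    exclusion rule observable, has its Ct shifted upward.
    """
    if noise_sd < 0 or not 0.0 <= melt_flag_fraction < 1.0:
        raise ConfigurationError("invalid noise_sd or melt_flag_fraction")
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    samples = sorted({s for s, _ in relative_levels})
    for sample in samples:
        genes = [g for (s, g) in relative_levels if s == sample]
        for gene in genes + [h for h in housekeeping if h not in genes]:
            if gene in housekeeping:
                base_ct = hk_baseline
            else:
                level = relative_levels[(sample, gene)]
                if level <= 0:
                    raise ConfigurationError(f"relative level must be > 0 for {(sample, gene)}")
                base_ct = hk_baseline - math.log2(level)
            for rep in range(1, n_reps + 1):
                flagged = bool(rng.random() < melt_flag_fraction) and gene not in housekeeping
                ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if flagged:
                    ct += 10.0  # off-target product: exclusion must not bias the mean
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "technical_rep": rep,
                        "ct": ct,
                        "melt_peaks": 2 if flagged else 1,
                    }
                )
    return pd.DataFrame(rows)
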