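"""Synthetic cell-line experiments, gene-set collections and patient cohorts.

The generators emulate the statistical structure of an acquired-resistance
transcriptomics study: three parental embryonal-carcinoma-like lines, each
with independently derived resistant clones profiled in biological
triplicate; a curated-style gene-set collection in which a minority of
"polycomb" sets concentrate on a planted pool of upregulated target genes;
and a tumor cohort whose disease-free-survival hazard depends on a latent
risk score expressed through the signature genes.

Every generator returns, alongside its data, a :class:`SimTruth` with the
planted ground truth, so downstream stages can be scored for recovery.  All
randomness flows from a single integer seed through ``numpy.random
.SeedSequence`` spawning: each generator derives independent child streams
for each logical source of noise, so identical config + seed reproduces
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .data_io import (
    ClinicalRecord,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GroupDesign,
    normalize_symbol,
)

import pandas as pd

__all__ = [
    "CellLineSimConfig",
    "CollectionSimConfig",
    "CohortSimConfig",
    "SimTruth",
    "generate_cellline_experiment",
    "generate_geneset_collection",
    "generate_patient_cohort",
]

DEFAULT_KEYWORD_TOKENS = ("PRC2", "PRC1", "H3K27", "EED", "SUZ12", "POLYCOMB")


@dataclass
class CellLineSimConfig:
    """Configuration for the parental/resistant count-matrix generator.

    Defaults mirror the study design being emulated: 3 parental lines with
    8, 4 and 2 independently derived resistant clones respectively, of
    which 10 are profiled, everything in biological triplicate, and a
    planted pool of 400 polycomb-target genes.  Each pool gene carries a
    Beta-distributed upregulation propensity with mean
    ``per_clone_target_fraction``, and each clone upregulates the gene with
    that probability — so most "core" pool genes rise in nearly every clone
    while the rest vary line to line, and each clone upregulates about 60%
    of the pool by a mean of 1.5 log2 units.  Counts are negative-binomial
    with log-normally distributed gene abundances.

    ``propensity_concentration`` is the Beta a+b: small values give a
    U-shaped propensity (strong core + strong line-to-line variability),
    large values make every gene's propensity ≈ the mean.
    """

    n_parental: int = 3
    clones_per_parental: tuple[int, ...] = (8, 4, 2)
    n_profiled: int = 10
    replicates: int = 3
    n_genes: int = 5000
    target_pool_size: int = 400
    per_clone_target_fraction: float = 0.6
    propensity_concentration: float = 0.35
    inclusion_sharpness: float = 0.2
    clone_family_sharing: float = 0.0
    target_log2fc: float = 1.5
    target_log2fc_sd: float = 0.75
    target_log2fc_min: float = 0.75
    dispersion: float = 0.1
    lib_size_mean: float = 2e6
    seed: int = 0

    def validate(self) -> None:
        if self.n_parental < 1 or self.replicates < 1 or self.n_genes < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.clones_per_parental) != self.n_parental:
            raise ValueError("clones_per_parental length must equal n_parental")
        if any(c < 1 for c in self.clones_per_parental):
            raise ValueError("each parental line needs >= 1 clone")
        if not (1 <= self.n_profiled <= sum(self.clones_per_parental)):
            raise ValueError("n_profiled must be in [1, total clone count]")
        if not (0 < self.per_clone_target_fraction <= 1):
            raise ValueError("per_clone_target_fraction must be in (0, 1]")
        if self.propensity_concentration <= 0:
            raise ValueError("propensity_concentration must be > 0")
        if not (0 <= self.clone_family_sharing <= 1):
            raise ValueError("clone_family_sharing must be in [0, 1]")
        if self.inclusion_sharpness <= 0:
            raise ValueError("inclusion_sharpness must be > 0")
        if self.target_log2fc < 0 or self.target_log2fc_sd < 0:
            raise ValueError("target_log2fc and target_log2fc_sd must be >= 0")
        if self.target_log2fc > 0 and not (0 <= self.target_log2fc_min <= self.target_log2fc):
            raise ValueError("target_log2fc_min must be in [0, target_log2fc]")
        if not (1 <= self.target_pool_size <= self.n_genes):
            raise ValueError("target_pool_size must be in [1, n_genes]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be > 0")


@dataclass
class CollectionSimConfig:
    """Configuration for the synthetic gene-set collection.

    Polycomb-labeled sets draw ``polycomb_overlap`` of their members from
    the planted target pool and carry a recognizable keyword token in their
    names; decoy sets are uniform draws from the background.  Set sizes stay
    within the usual GSEA filter bounds (15–500).
    """

    n_polycomb_sets: int = 10
    n_decoy_sets: int = 200
    set_size_range: tuple[int, int] = (25, 150)
    polycomb_overlap: float = 0.8
    keyword_tokens: tuple[str, ...] = DEFAULT_KEYWORD_TOKENS
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.set_size_range
        if not (15 <= lo <= hi <= 500):
            raise ValueError("set_size_range must lie within [15, 500]")
        if not (0 <= self.polycomb_overlap <= 1):
            raise ValueError("polycomb_overlap must be in [0, 1]")
        if self.n_polycomb_sets < 0 or self.n_decoy_sets < 0:
            raise ValueError("set counts must be >= 0")
        if self.n_polycomb_sets > 0 and not self.keyword_tokens:
            raise ValueError("need at least one keyword token")


@dataclass
class CohortSimConfig:
    """Configuration for the synthetic patient cohort.

    Each patient carries a standard-normal latent risk score; signature-gene
    expression equals the score plus per-gene Gaussian noise and other genes
    are pure noise.  Survival is exponential with the hazard multiplied by
    ``group_hazard_ratio`` for patients above the latent-score median, with
    uniform censoring on (0, ``censoring_time_max``].  When
    ``baseline_hazard`` is None it is calibrated by root-finding so the
    expected number of events equals ``target_event_count``.
    """

    n_patients: int = 132
    target_event_count: float = 34.0
    group_hazard_ratio: float = 2.1
    signature_expression_sd: float = 1.0
    baseline_hazard: float | None = None
    censoring_time_max: float = 120.0
    n_background_genes: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if self.group_hazard_ratio <= 0:
            raise ValueError("group_hazard_ratio must be > 0")
        if self.signature_expression_sd < 0:
            raise ValueError("signature_expression_sd must be >= 0")
        if self.censoring_time_max <= 0:
            raise ValueError("censoring_time_max must be > 0")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 < self.target_event_count < self.n_patients):
            raise ValueError("target_event_count must be in (0, n_patients)")


@dataclass
class SimTruth:
    """Planted ground truth carried alongside generated data."""

    gene_universe: list[str] = field(default_factory=list)
    target_pool: list[str] = field(default_factory=list)
    per_clone_targets: dict[str, list[str]] = field(default_factory=dict)
    polycomb_set_names: list[str] = field(default_factory=list)
    patient_latent_scores: dict[str, float] = field(default_factory=dict)
    patient_true_group: dict[str, str] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_cellline_experiment(
    config: CellLineSimConfig,
) -> tuple[ExpressionMatrix, dict[str, GroupDesign], SimTruth]:
    """Simulate the parental-vs-resistant count matrix.

    Returns one counts matrix holding all parental and clone replicates, a
    :class:`GroupDesign` for each of the ``n_profiled`` randomly chosen
    clones (contrasting the clone's replicates against its parental line's
    replicates), and the planted truth — the target pool and every clone's
    upregulated subset.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    r_means, r_pool, r_clone, r_profile, r_lib, r_counts = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    genes = _gene_names(config.n_genes)
    abundance = r_means.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    rel_abundance = abundance / abundance.sum()

    pool_idx = np.sort(
        r_pool.choice(config.n_genes, size=config.target_pool_size, replace=False)
    )
    pool = [genes[i] for i in pool_idx]

    parental_lines = [f"P{i + 1}" for i in range(config.n_parental)]
    clones: list[tuple[str, str]] = []  # (clone name, parental line)
    for line, n_clones in zip(parental_lines, config.clones_per_parental):
        for j in range(n_clones):
            clones.append((f"{line}-R{j + 1}", line))

    # per-gene upregulation propensity, shared across clones
    f = config.per_clone_target_fraction
    s = config.propensity_concentration
    if f >= 1.0:
        propensity = np.ones(config.target_pool_size)
    else:
        propensity = r_clone.beta(s * f, s * (1.0 - f), size=config.target_pool_size)
    # Each clone derepresses gene g to a graded level w in [0, 1], Beta-
    # distributed around the gene's propensity (inclusion_sharpness = Beta
    # a+b; larger = each clone tracks the propensity more faithfully).  A
    # gene counts as planted in a clone when w >= 0.5, so per-clone planted
    # fractions concentrate near per_clone_target_fraction while the exact
    # subsets vary line to line.  Clones from a common parental pool may
    # additionally copy their family's level draw with probability
    # clone_family_sharing.
    nu = config.inclusion_sharpness
    pi_safe = np.clip(propensity, 1e-6, 1.0 - 1e-6)
    family_level = {
        line: r_clone.beta(nu * pi_safe, nu * (1.0 - pi_safe))
        for line in parental_lines
    }
    rho = config.clone_family_sharing
    per_clone_targets: dict[str, np.ndarray] = {}
    clone_level: dict[str, np.ndarray] = {}
    for clone, parent in clones:
        own = r_clone.beta(nu * pi_safe, nu * (1.0 - pi_safe))
        if rho > 0:
            use_family = r_clone.random(config.target_pool_size) < rho
            level = np.where(use_family, family_level[parent], own)
        else:
            level = own
        clone_level[clone] = level
        per_clone_targets[clone] = pool_idx[level >= 0.5]

    # gene-specific planted effect magnitudes, shared across clones:
    # a floor plus a heavy-tailed gamma excess, mean target_log2fc overall
    excess_mean = config.target_log2fc - config.target_log2fc_min
    if config.target_log2fc == 0 or config.target_log2fc_sd == 0 or excess_mean == 0:
        gene_lfc = np.full(config.target_pool_size, config.target_log2fc)
    else:
        shape = (excess_mean / config.target_log2fc_sd) ** 2
        scale = config.target_log2fc_sd**2 / excess_mean
        gene_lfc = config.target_log2fc_min + r_clone.gamma(
            shape, scale, size=config.target_pool_size
        )
    # realized per-clone, per-gene log2 shift = gene magnitude x graded
    # level, rescaled so the mean shift over planted (level >= 0.5) entries
    # equals target_log2fc exactly
    clone_shift = {clone: gene_lfc * clone_level[clone] for clone in clone_level}
    if config.target_log2fc > 0:
        planted_shifts = np.concatenate(
            [clone_shift[c][clone_level[c] >= 0.5] for c in clone_shift]
        )
        if planted_shifts.size and planted_shifts.mean() > 0:
            rescale = config.target_log2fc / planted_shifts.mean()
            clone_shift = {c: s * rescale for c, s in clone_shift.items()}

    sample_lines = [(line, line) for line in parental_lines] + clones
    columns: list[str] = []
    col_owner: list[str] = []
    for name, _parent in sample_lines:
        for rep in range(1, config.replicates + 1):
            columns.append(f"{name}_rep{rep}")
            col_owner.append(name)

    n_samples = len(columns)
    lib_sizes = config.lib_size_mean * r_lib.lognormal(0.0, 0.1, size=n_samples)

    mu = np.outer(rel_abundance, lib_sizes)
    for j, owner in enumerate(col_owner):
        if owner in clone_shift:
            mu[pool_idx, j] *= 2.0 ** clone_shift[owner]

    size_param = 1.0 / config.dispersion  # NB "n" with var = mu + dispersion * mu^2
    p_param = size_param / (size_param + mu)
    counts = r_counts.negative_binomial(size_param, p_param)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=genes, columns=columns), "counts"
    )

    clone_names = [c for c, _ in clones]
    profiled_idx = np.sort(
        r_profile.choice(len(clone_names), size=config.n_profiled, replace=False)
    )
    profiled = [clones[i] for i in profiled_idx]

    designs: dict[str, GroupDesign] = {}
    for clone, parent in profiled:
        assignment = {c: parent for c, o in zip(columns, col_owner) if o == parent}
        assignment.update({c: clone for c, o in zip(columns, col_owner) if o == clone})
        designs[clone] = GroupDesign(assignment, reference_group=parent, test_group=clone)

    truth = SimTruth(
        gene_universe=genes,
        target_pool=pool,
        per_clone_targets={c: [genes[i] for i in idx] for c, idx in per_clone_targets.items()},
    )
    return matrix, designs, truth


def generate_geneset_collection(
    config: CollectionSimConfig, truth: SimTruth
) -> tuple[GeneSetCollection, SimTruth]:
    """Simulate a curated-style collection with planted polycomb sets.

    Polycomb sets draw ``polycomb_overlap`` of their members uniformly from
    ``truth.target_pool`` and the remainder from the background; decoy sets
    are uniform background draws.  Returns the collection and an updated
    truth whose ``polycomb_set_names`` records the planted labels.
    """
    config.validate()
    if not truth.target_pool:
        raise ValueError("truth.target_pool is empty; generate the cell-line experiment first")
    if not truth.gene_universe:
        raise ValueError("truth.gene_universe is empty")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    universe = np.asarray(truth.gene_universe)
    pool = np.asarray(truth.target_pool)
    background = np.asarray(sorted(set(universe) - set(pool)))
    lo, hi = config.set_size_range

    sets: list[GeneSet] = []
    polycomb_names: list[str] = []
    # polycomb-target collections are among the larger curated sets, so the
    # planted sets draw from the upper half of the size range
    poly_lo = (lo + hi) // 2
    for i in range(config.n_polycomb_sets):
        token = config.keyword_tokens[i % len(config.keyword_tokens)]
        name = f"{token}_TARGETS_UP_{i + 1:02d}"
        size = int(rng.integers(poly_lo, hi + 1))
        n_pool = int(round(config.polycomb_overlap * size))
        if n_pool > len(pool):
            raise ValueError(
                f"target pool ({len(pool)}) smaller than required overlap ({n_pool})"
            )
        members = list(rng.choice(pool, size=n_pool, replace=False))
        members += list(rng.choice(background, size=size - n_pool, replace=False))
        sets.append(GeneSet(name, "synthetic polycomb-target set", frozenset(members)))
        polycomb_names.append(name)

    for i in range(config.n_decoy_sets):
        name = f"DECOY_PATHWAY_{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(background, size=size, replace=False)
        sets.append(GeneSet(name, "synthetic decoy set", frozenset(members)))

    collection = GeneSetCollection(sets)
    return collection, replace(truth, polycomb_set_names=polycomb_names)


def _event_probability(lam: float, censor_max: float) -> float:
    """P(event observed) for exponential(lam) time with U(0, censor_max] censoring."""
    x = lam * censor_max
    return 1.0 - (1.0 - math.exp(-x)) / x


def calibrate_baseline_hazard(config: CohortSimConfig) -> float:
    """Solve for the baseline hazard giving the target expected event count."""
    n_high = config.n_patients // 2
    n_low = config.n_patients - n_high
    hr = config.group_hazard_ratio

    def expected_events(b: float) -> float:
        return n_low * _event_probability(b, config.censoring_time_max) + n_high * (
            _event_probability(b * hr, config.censoring_time_max)
        )

    target = float(config.target_event_count)
    return brentq(lambda b: expected_events(b) - target, 1e-10, 1e4, xtol=1e-14, rtol=1e-12)


def generate_patient_cohort(
    config: CohortSimConfig, signature_genes: Sequence[str]
) -> tuple[ExpressionMatrix, list[ClinicalRecord], SimTruth]:
    """Simulate a tumor cohort whose hazard tracks a latent signature score.

    Each patient draws a latent score z ~ N(0, 1).  Every signature gene's
    expression is z plus independent N(0, ``signature_expression_sd``²)
    noise; ``n_background_genes`` extra genes are pure N(0, 1) noise.
    Survival is exponential with hazard ``baseline · HR^{I(z > median z)}``
    and uniform censoring, so the generator's hazard ratio is exactly the
    estimand the median-split log-rank pipeline targets.
    """
    config.validate()
    signature_genes = [normalize_symbol(g) for g in signature_genes]
    if len(set(signature_genes)) != len(signature_genes):
        raise ValueError("signature_genes contains duplicates")
    if len(signature_genes) < 10:
        raise ValueError("need >= 10 signature genes")

    root = np.random.SeedSequence(config.seed)
    r_z, r_expr, r_surv = (np.random.default_rng(s) for s in root.spawn(3))

    n = config.n_patients
    patients = [f"PT{i + 1:04d}" for i in range(n)]
    z = r_z.standard_normal(n)
    high = z > np.median(z)

    sig_rows = z[None, :] + config.signature_expression_sd * r_expr.standard_normal(
        (len(signature_genes), n)
    )
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    bg_rows = r_expr.standard_normal((config.n_background_genes, n))

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([sig_rows, bg_rows]),
            index=signature_genes + bg_genes,
            columns=patients,
        ),
        "logcpm",
    )

    baseline = (
        config.baseline_hazard
        if config.baseline_hazard is not None
        else calibrate_baseline_hazard(config)
    )
    lam = baseline * np.where(high, config.group_hazard_ratio, 1.0)
    t_event = r_surv.exponential(1.0 / lam)
    # uniform on (0, C]: 1 - U gives the half-open interval away from zero
    t_cens = (1.0 - r_surv.random(n)) * config.censoring_time_max
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    records = [
        ClinicalRecord(pid, float(t), int(e)) for pid, t, e in zip(patients, time, event)
    ]
    truth = SimTruth(
        gene_universe=signature_genes + bg_genes,
        patient_latent_scores=dict(zip(patients, map(float, z))),
        patient_true_group={p: ("high" if h else "low") for p, h in zip(patients, high)},
    )
    return matrix, records, truth
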