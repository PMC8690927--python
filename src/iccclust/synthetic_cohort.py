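"""Synthetic multi-cohort generator with closed-form association oracles.

The generator follows a cluster-first model: each sample draws a latent
sub-cluster label (1A, 1B, 2A, 2B, 2C or 3), then its seven clustering-gene
states conditionally independently given the label, subject to the label's
defining constraint (e.g. a 1B sample carries at least one TP53/SMAD4
mutation and wild-type KRAS).  Rare Cluster1/Cluster2 double mutants arise
from a per-gene "co-mutant leak" probability on the opposite gene set.
Passenger genes mutate independently of the label.  Clinical covariates
(CA19-9, stage, IHC markers, histology), outcomes (Weibull survival),
signature-shifted expression and delta-beta-shifted methylation all condition
on the label, so every downstream analysis stage has a planted truth.

Because each sub-cluster's genotype distribution is an explicit finite
mixture over the 2^7 genotype patterns, pairwise joint probabilities -- and
hence the odds ratio any co-occurrence analysis should converge to -- are
available in closed form via :func:`analytic_pair_or`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_rules import C1_GENES, C2_GENES, SEVEN_GENES
from .cohort_io import MutationMatrix, _as_status_frame
from .errors import ValidationError
from .expr_signatures import SignatureSet

SUBCLUSTERS = ("1A", "1B", "2A", "2B", "2C", "3")
CLUSTER_OF = {"1A": "C1", "1B": "C1", "2A": "C2", "2B": "C2", "2C": "C2", "3": "C3"}

#: Gene set that must contain at least one mutation for the label to be valid.
REQUIRED_SETS = {
    "1A": ("KRAS",),
    "1B": ("TP53", "SMAD4"),
    "2A": ("IDH1", "IDH2"),
    "2B": ("FGFR2_fusion",),
    "2C": ("BAP1",),
    "3": (),
}


def default_mixing() -> dict[str, float]:
    """Sub-cluster proportions reproducing 33.1% Cluster1 / 23.2% Cluster2 / 43.7% Cluster3."""
    return {"1A": 0.199, "1B": 0.132, "2A": 0.116, "2B": 0.058, "2C": 0.058, "3": 0.437}


def default_gene_probs(leak: float) -> dict[str, dict[str, float]]:
    """Per-sub-cluster Bernoulli mutation probabilities for the seven clustering genes.

    ``leak`` is the per-gene probability of carrying a mutation from the
    opposite cluster's gene set, generating the rare Cluster1/2 co-mutants.
    """
    return {
        "1A": {"KRAS": 1.0, "TP53": 0.5, "SMAD4": 0.25, "IDH1": leak, "IDH2": leak, "FGFR2_fusion": leak, "BAP1": leak},
        "1B": {"KRAS": 0.0, "TP53": 0.8, "SMAD4": 0.4, "IDH1": leak, "IDH2": leak, "FGFR2_fusion": leak, "BAP1": leak},
        "2A": {"KRAS": leak, "TP53": leak, "SMAD4": leak, "IDH1": 0.7, "IDH2": 0.35, "FGFR2_fusion": 0.05, "BAP1": 0.3},
        "2B": {"KRAS": leak, "TP53": leak, "SMAD4": leak, "IDH1": 0.0, "IDH2": 0.0, "FGFR2_fusion": 1.0, "BAP1": 0.3},
        "2C": {"KRAS": leak, "TP53": leak, "SMAD4": leak, "IDH1": 0.0, "IDH2": 0.0, "FGFR2_fusion": 0.0, "BAP1": 1.0},
        "3": {g: 0.0 for g in SEVEN_GENES},
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults encode the emulated study conditions."""

    n_samples: int = 500
    seed: int = 0
    mixing: dict[str, float] = field(default_factory=default_mixing)
    comutant_leak: float = 0.01
    gene_probs: dict[str, dict[str, float]] | None = None
    passenger_probs: dict[str, float] = field(
        default_factory=lambda: {"ARID1A": 0.15, "PBRM1": 0.12, "CDKN2A": 0.09, "PIK3CA": 0.07, "EPHA2": 0.05}
    )

    # mutation burden (non-synonymous counts)
    tmb_mean: dict[str, float] = field(
        default_factory=lambda: {"1A": 60.0, "1B": 120.0, "2A": 45.0, "2B": 45.0, "2C": 45.0, "3": 45.0}
    )
    hypermutator_fraction: float = 0.02
    hypermutator_extra_mean: float = 250.0  # count = 301 + Poisson(extra)

    # assay coverage masks
    panel_fraction: float = 0.0  # panel samples lack nonsyn counts
    fgfr2_fusion_coverage: float = 0.9  # fraction of samples assayed for the fusion

    # clinical covariates, per sub-cluster
    ca199_log_median: dict[str, float] = field(
        default_factory=lambda: {
            "1A": math.log(300.0), "1B": math.log(150.0),
            "2A": math.log(30.0), "2B": math.log(30.0), "2C": math.log(30.0),
            "3": math.log(80.0),
        }
    )
    ca199_log_sd: float = 1.0
    stage34_prob: dict[str, float] = field(
        default_factory=lambda: {"1A": 0.70, "1B": 0.60, "2A": 0.55, "2B": 0.55, "2C": 0.55, "3": 0.50}
    )
    comutant_stage34_prob: float = 0.875
    s100p_pos: dict[str, float] = field(
        default_factory=lambda: {"1A": 0.85, "1B": 0.70, "2A": 0.05, "2B": 0.05, "2C": 0.05, "3": 0.40}
    )
    krt17_pos: dict[str, float] = field(
        default_factory=lambda: {"1A": 0.80, "1B": 0.65, "2A": 0.05, "2B": 0.05, "2C": 0.05, "3": 0.40}
    )
    large_duct_prob: dict[str, float] = field(
        default_factory=lambda: {"1A": 0.85, "1B": 0.70, "2A": 0.10, "2B": 0.10, "2C": 0.10, "3": 0.45}
    )
    east_prob: dict[str, float] = field(
        default_factory=lambda: {"1A": 0.75, "1B": 0.70, "2A": 0.35, "2B": 0.35, "2C": 0.35, "3": 0.50}
    )
    metastasis_prob: dict[str, float] = field(
        default_factory=lambda: {"1A": 0.30, "1B": 0.30, "2A": 0.20, "2B": 0.20, "2C": 0.20, "3": 0.15}
    )

    # survival (Weibull per cluster, months; administrative censoring)
    os_scale: dict[str, float] = field(default_factory=lambda: {"C1": 20.0, "C2": 55.0, "C3": 38.0})
    rfs_scale_factor: float = 0.6
    weibull_shape: float = 1.1
    censor_time: float = 60.0

    # expression
    n_signature_genes: int = 25
    n_null_genes: int = 50
    expression_effect: float = 1.0  # log2-SD shift on signature genes
    discriminator_shift: float = 3.0  # log2 shift on S100P/KRT17 in IHC-positive samples

    # methylation
    n_probes: int = 200
    n_diff_probes: int = 50
    delta_beta: float = 0.25
    beta_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.gene_probs is None:
            self.gene_probs = default_gene_probs(self.comutant_leak)
        self.validate()

    def validate(self) -> None:
        pi = np.array([self.mixing.get(s, 0.0) for s in SUBCLUSTERS], dtype=float)
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
            raise ValidationError("mixing proportions must sum to 1")
        if (pi < 0).any():
            raise ValidationError("mixing proportions must be non-negative")
        for sub in SUBCLUSTERS:
            probs = self.gene_probs[sub]
            for g in SEVEN_GENES:
                p = probs[g]
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"gene probability out of range: {sub}/{g}={p}")
            required = REQUIRED_SETS[sub]
            if required and all(probs[g] == 0.0 for g in required):
                raise ValidationError(f"sub-cluster {sub} cannot realise its defining set")
        for p in self.passenger_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("passenger probabilities must lie in [0, 1]")
        if not 0.0 <= self.comutant_leak <= 1.0:
            raise ValidationError("comutant_leak must lie in [0, 1]")


_PATTERNS = np.array(list(itertools.product((0, 1), repeat=len(SEVEN_GENES))), dtype=np.int8)


def genotype_distribution(config: SyntheticConfig, sub: str) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution over the 2^7 seven-gene genotypes for one sub-cluster.

    Conditionally independent Bernoulli draws, renormalised over the
    patterns where the sub-cluster's defining gene set carries at least one
    mutation (the defining constraint has probability zero of failing).
    """
    probs = np.array([config.gene_probs[sub][g] for g in SEVEN_GENES], dtype=float)
    w = np.prod(np.where(_PATTERNS == 1, probs, 1.0 - probs), axis=1)
    required = REQUIRED_SETS[sub]
    if required:
        idx = [SEVEN_GENES.index(g) for g in required]
        w = np.where(_PATTERNS[:, idx].sum(axis=1) > 0, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValidationError(f"sub-cluster {sub} has no admissible genotype")
    return _PATTERNS, w / total


def _gene_marginals(config: SyntheticConfig) -> pd.DataFrame:
    """P(gene mutant | sub-cluster) for the seven genes (rows) x sub-clusters."""
    cols = {}
    for sub in SUBCLUSTERS:
        patterns, w = genotype_distribution(config, sub)
        cols[sub] = patterns.T @ w
    return pd.DataFrame(cols, index=list(SEVEN_GENES))


def analytic_marginal(config: SyntheticConfig, gene: str) -> float:
    """Exact population mutation frequency of a gene under the mixture."""
    if gene in SEVEN_GENES:
        marg = _gene_marginals(config).loc[gene]
        return float(sum(config.mixing[s] * marg[s] for s in SUBCLUSTERS))
    if gene in config.passenger_probs:
        return float(config.passenger_probs[gene])
    raise ValidationError(f"gene {gene!r} not configured")


def _joint_prob(config: SyntheticConfig, gene_a: str, gene_b: str) -> float:
    """P(both mutant) under the mixture; passengers are label-independent."""
    in7_a, in7_b = gene_a in SEVEN_GENES, gene_b in SEVEN_GENES
    if in7_a and in7_b:
        ia, ib = SEVEN_GENES.index(gene_a), SEVEN_GENES.index(gene_b)
        total = 0.0
        for sub in SUBCLUSTERS:
            patterns, w = genotype_distribution(config, sub)
            both = (patterns[:, ia] == 1) & (patterns[:, ib] == 1)
            total += config.mixing[sub] * w[both].sum()
        return total
    if not in7_a and not in7_b:
        return analytic_marginal(config, gene_a) * analytic_marginal(config, gene_b)
    seven, other = (gene_a, gene_b) if in7_a else (gene_b, gene_a)
    return analytic_marginal(config, seven) * analytic_marginal(config, other)


def analytic_pair_or(config: SyntheticConfig, gene_a: str, gene_b: str) -> float:
    """Exact odds ratio of the 2x2 probability table implied by the mixture."""
    pa = analytic_marginal(config, gene_a)
    pb = analytic_marginal(config, gene_b)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValidationError("odds ratio undefined for a degenerate marginal")
    p11 = _joint_prob(config, gene_a, gene_b)
    p10 = pa - p11
    p01 = pb - p11
    p00 = 1.0 - pa - pb + p11
    if p10 * p01 == 0.0:
        return math.inf if p11 * p00 > 0 else 0.0
    return (p11 * p00) / (p10 * p01)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """One simulated cohort: every data modality plus the generating truth."""

    mutations: MutationMatrix
    clinical: pd.DataFrame
    expression: pd.DataFrame
    beta: pd.DataFrame
    labels: pd.Series  # true sub-cluster per sample
    signatures: dict[str, SignatureSet]
    config: SyntheticConfig

    @property
    def clusters(self) -> pd.Series:
        """True cluster (C1/C2/C3) per sample."""
        return self.labels.map(CLUSTER_OF).rename("cluster")

    def write(self, outdir) -> dict[str, str]:
        """Dump all modalities as TSV/GMT into a directory; returns the paths."""
        from pathlib import Path

        from .cohort_io import write_matrix
        from .expr_signatures import write_gmt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "matrix.tsv",
            "counts": outdir / "counts.tsv",
            "clinical": outdir / "clinical.tsv",
            "expression": outdir / "expression.tsv",
            "beta": outdir / "beta.tsv",
            "labels": outdir / "labels.tsv",
            "signatures": outdir / "signatures.gmt",
        }
        write_matrix(self.mutations, paths["matrix"], paths["counts"])
        self.clinical.to_csv(paths["clinical"], sep="\t", na_rep="NA", index_label="sample_id")
        self.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
        self.beta.to_csv(paths["beta"], sep="\t", na_rep="NA", index_label="probe_id")
        frame = pd.DataFrame({"subcluster": self.labels, "cluster": self.clusters})
        frame.to_csv(paths["labels"], sep="\t", index_label="sample_id")
        write_gmt({s.name: list(s.up) for s in self.signatures.values()}, paths["signatures"])
        return {k: str(v) for k, v in paths.items()}


def _bernoulli_by_label(rng, labels: np.ndarray, probs: dict[str, float]) -> np.ndarray:
    p = np.array([probs[s] for s in labels], dtype=float)
    return rng.random(labels.size) < p


def simulate(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; bit-identical under an identical config."""
    config.validate()
    n = config.n_samples
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_mut, rng_assay, rng_clin, rng_surv, rng_expr, rng_meth = (np.random.default_rng(s) for s in streams)

    samples = [f"SYN{i + 1:05d}" for i in range(n)]
    pi = [config.mixing[s] for s in SUBCLUSTERS]
    labels = rng_mut.choice(SUBCLUSTERS, size=n, p=pi)

    # seven-gene genotypes from the per-label pattern mixtures
    genotype = np.zeros((n, len(SEVEN_GENES)), dtype=np.int8)
    for sub in SUBCLUSTERS:
        idx = np.flatnonzero(labels == sub)
        if idx.size == 0:
            continue
        patterns, w = genotype_distribution(config, sub)
        choice = rng_mut.choice(len(w), size=idx.size, p=w)
        genotype[idx] = patterns[choice]

    passenger_names = list(config.passenger_probs)
    passengers = np.column_stack(
        [rng_mut.random(n) < config.passenger_probs[g] for g in passenger_names]
    ).astype(np.int8) if passenger_names else np.zeros((n, 0), dtype=np.int8)

    status = np.concatenate([genotype, passengers], axis=1).astype(float)
    genes = list(SEVEN_GENES) + passenger_names

    # assay masks: the fusion pseudo-gene is not covered for every sample
    fus_assayed = rng_assay.random(n) < config.fgfr2_fusion_coverage
    status[~fus_assayed, SEVEN_GENES.index("FGFR2_fusion")] = np.nan

    # non-synonymous counts with a hypermutator tail; panel samples lack counts
    tmb = np.array([rng_assay.poisson(config.tmb_mean[s]) for s in labels], dtype=float)
    hyper = rng_assay.random(n) < config.hypermutator_fraction
    tmb[hyper] = 301 + rng_assay.poisson(config.hypermutator_extra_mean, size=int(hyper.sum()))
    panel = rng_assay.random(n) < config.panel_fraction
    tmb[panel] = np.nan

    mutations = MutationMatrix(
        _as_status_frame(status, samples, genes),
        pd.Series(tmb, index=samples),
    )

    # --- clinical covariates conditioned on the latent label ---------------
    c1_any = genotype[:, [SEVEN_GENES.index(g) for g in C1_GENES]].any(axis=1)
    c2_any = genotype[:, [SEVEN_GENES.index(g) for g in C2_GENES]].any(axis=1)
    co_mutant = c1_any & c2_any

    ca199 = rng_clin.lognormal(
        mean=np.array([config.ca199_log_median[s] for s in labels]), sigma=config.ca199_log_sd
    )
    p34 = np.array([config.stage34_prob[s] for s in labels])
    p34[co_mutant] = config.comutant_stage34_prob
    high_stage = rng_clin.random(n) < p34
    stage = np.where(
        high_stage,
        np.where(rng_clin.random(n) < 0.5, "III", "IV"),
        np.where(rng_clin.random(n) < 0.5, "I", "II"),
    )
    s100p = _bernoulli_by_label(rng_clin, labels, config.s100p_pos)
    krt17 = _bernoulli_by_label(rng_clin, labels, config.krt17_pos)
    large_duct = _bernoulli_by_label(rng_clin, labels, config.large_duct_prob)
    east = _bernoulli_by_label(rng_clin, labels, config.east_prob)
    metastasis = _bernoulli_by_label(rng_clin, labels, config.metastasis_prob)
    sex = np.where(rng_clin.random(n) < 0.55, "M", "F")
    age = np.clip(rng_clin.normal(62, 10, size=n), 18, 90).round(1)
    etiology_levels = np.array(["none", "viral_hepatitis", "liver_fluke", "hepatolithiasis"])
    etiology_probs = {
        "C1": [0.30, 0.35, 0.20, 0.15],
        "C2": [0.70, 0.20, 0.05, 0.05],
        "C3": [0.50, 0.30, 0.10, 0.10],
    }
    clusters = np.array([CLUSTER_OF[s] for s in labels])
    etiology = np.empty(n, dtype=object)
    for cl, probs in etiology_probs.items():
        idx = np.flatnonzero(clusters == cl)
        if idx.size:
            etiology[idx] = rng_clin.choice(etiology_levels, size=idx.size, p=probs)

    # --- outcomes -----------------------------------------------------------
    def draw_survival(scale_by_cluster: dict[str, float], factor: float = 1.0):
        scale = np.array([scale_by_cluster[c] for c in clusters]) * factor
        t = scale * rng_surv.weibull(config.weibull_shape, size=n)
        censor = rng_surv.uniform(3.0, config.censor_time, size=n)
        event = (t <= censor).astype(int)
        return np.minimum(t, censor).round(2), event

    os_months, os_event = draw_survival(config.os_scale)
    rfs_months, rfs_event = draw_survival(config.os_scale, config.rfs_scale_factor)

    clinical = pd.DataFrame(
        {
            "cohort": "SYN",
            "region": np.where(east, "East", "West"),
            "etiology": etiology,
            "sex": sex,
            "age": age,
            "ca19_9": ca199.round(1),
            "stage": stage,
            "tumor_site": np.where(metastasis, "metastasis", "primary"),
            "histology": np.where(large_duct, "large-duct", "small-duct"),
            "s100p": np.where(s100p, "pos", "neg"),
            "krt17": np.where(krt17, "pos", "neg"),
            "os_months": os_months,
            "os_event": os_event,
            "rfs_months": rfs_months,
            "rfs_event": rfs_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # --- expression ---------------------------------------------------------
    k = config.n_signature_genes
    poor = [f"POOR{i + 1:03d}" for i in range(k)]
    good = [f"GOOD{i + 1:03d}" for i in range(k)]
    cd = [f"CD{i + 1:03d}" for i in range(k)]
    hpsc = [f"HPSC{i + 1:03d}" for i in range(k)]
    nulls = [f"NULL{i + 1:03d}" for i in range(config.n_null_genes)]
    expr_genes = poor + good + cd + hpsc + ["S100P", "KRT17"] + nulls
    expr = 8.0 + rng_expr.normal(0.0, 1.0, size=(len(expr_genes), n))
    expression = pd.DataFrame(expr, index=expr_genes, columns=samples)
    is_c1 = clusters == "C1"
    is_c2 = clusters == "C2"
    e = config.expression_effect
    expression.loc[poor, is_c1] += e
    expression.loc[good, is_c2] += e
    expression.loc[cd, is_c2] += e
    expression.loc[hpsc, is_c2] += e
    expression.loc["S100P", s100p] += config.discriminator_shift
    expression.loc["KRT17", krt17] += config.discriminator_shift
    expression = expression.round(4)

    signatures = {
        "poor_prognosis": SignatureSet("poor_prognosis", up=tuple(poor)),
        "good_prognosis": SignatureSet("good_prognosis", up=tuple(good)),
        "cd": SignatureSet("cd", up=tuple(cd)),
        "hpsc": SignatureSet("hpsc", up=tuple(hpsc)),
    }

    # --- methylation --------------------------------------------------------
    idh_mut = genotype[:, SEVEN_GENES.index("IDH1")] | genotype[:, SEVEN_GENES.index("IDH2")]
    beta = _beta_block(
        n_samples=n,
        mutant_mask=idh_mut.astype(bool),
        n_probes=config.n_probes,
        n_diff=config.n_diff_probes,
        delta_beta=config.delta_beta,
        sigma=config.beta_sigma,
        rng=rng_meth,
        columns=samples,
    )

    return SyntheticCohort(
        mutations=mutations,
        clinical=clinical,
        expression=expression,
        beta=beta,
        labels=pd.Series(labels, index=samples, name="subcluster"),
        signatures=signatures,
        config=config,
    )


def _beta_block(n_samples, mutant_mask, n_probes, n_diff, delta_beta, sigma, rng, columns):
    # Probe base levels vary across probes and the planted shift alternates in
    # sign (hyper- and hypo-methylated in mutants), so the two group centroids
    # have distinct shapes and correlation-based classification is well posed.
    if n_diff > n_probes:
        raise ValidationError("n_diff cannot exceed n_probes")
    probes = [f"cg{i + 1:06d}" for i in range(n_probes)]
    base = rng.uniform(0.35, 0.65, size=n_probes)
    base[:n_diff] = rng.uniform(0.30, 0.55, size=n_diff)
    means = np.tile(base[:, None], (1, n_samples))
    direction = np.where(np.arange(n_diff) % 2 == 0, 1.0, -1.0)
    mut_cols = np.flatnonzero(mutant_mask)
    if mut_cols.size:
        means[np.ix_(np.arange(n_diff), mut_cols)] += (direction * delta_beta)[:, None]
    beta = np.clip(means + rng.normal(0.0, sigma, size=means.shape), 0.0, 1.0)
    return pd.DataFrame(beta.round(4), index=probes, columns=list(columns))


def simulate_beta(
    n_mut: int,
    n_wt: int,
    n_probes: int = 200,
    n_diff: int = 50,
    delta_beta: float = 0.25,
    sigma: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Stand-alone beta matrix with planted differential probes.

    Returns ``(beta, mutant_samples, diff_probes)``: the first ``n_diff``
    probes are shifted by ``delta_beta`` (alternating hyper/hypo) in the
    mutant group, the rest are null.  Useful for calibrating the
    differential-methylation caller.
    """
    rng = np.random.default_rng(seed)
    n = n_mut + n_wt
    columns = [f"M{i + 1:03d}" for i in range(n_mut)] + [f"W{i + 1:03d}" for i in range(n_wt)]
    mask = np.zeros(n, dtype=bool)
    mask[:n_mut] = True
    beta = _beta_block(n, mask, n_probes, n_diff, delta_beta, sigma, rng, columns)
    return beta, columns[:n_mut], list(beta.index[:n_diff])


def simulate_survival_cohort(
    n: int = 500,
    hazard_ratio: float = 2.0,
    baseline_rate: float = 1.0 / 30.0,
    censor_time: float = 60.0,
    covariate_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival cohort with one binary covariate of known hazard ratio.

    Administrative censoring at ``censor_time`` months.  Columns: ``x``
    (0/1 covariate), ``time``, ``event``.
    """
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < covariate_prob).astype(int)
    rate = baseline_rate * hazard_ratio ** x
    t = rng.exponential(1.0 / rate)
    event = (t <= censor_time).astype(int)
    return pd.DataFrame({"x": x, "time": np.minimum(t, censor_time), "event": event})


def null_matrix(n_samples: int, n_genes: int, frequency: float = 0.5, seed: int = 0) -> MutationMatrix:
    """Fully independent mutation matrix -- the null for pairwise association tests."""
    rng = np.random.default_rng(seed)
    values = (rng.random((n_samples, n_genes)) < frequency).astype(float)
    samples = [f"N{i + 1:05d}" for i in range(n_samples)]
    genes = [f"G{j + 1:03d}" for j in range(n_genes)]
    return MutationMatrix(_as_status_frame(values, samples, genes))
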