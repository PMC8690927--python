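"""All-pairs co-occurrence / mutual-exclusivity statistics over a mutation matrix.

Each unordered gene pair is summarised by its 2x2 table over
pairwise-complete samples (both genes assayed), the sample odds ratio
``(n11 * n00) / (n10 * n01)`` -- reported as 0 or +inf for zero cells, with
no continuity correction -- and a two-sided Fisher exact p-value (sum of
hypergeometric probabilities no larger than that of the observed table).
Family-wise q-values come from Benjamini-Hochberg step-up control over all
tested pairs of one run; significant pairs (q below threshold, odds ratio
different from 1) form the signed edges of a co-mutation network.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import MUT, WT, MutationMatrix, _as_status_frame
from .errors import UndefinedPairError, ValidationError

CO_OCCURRENCE = "co-occurrence"
EXCLUSIVITY = "exclusivity"
NO_DIRECTION = "none"


def sample_odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    """Cross-product odds ratio with 0 / +inf for zero cells, NaN for 0/0."""
    num = n11 * n00
    den = n10 * n01
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


@dataclass
class PairAssociation:
    """One gene pair's 2x2 counts and association statistics."""

    gene_a: str
    gene_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None

    @property
    def n(self) -> int:
        """Number of pairwise-complete samples."""
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def direction(self) -> str:
        if math.isnan(self.odds_ratio) or self.odds_ratio == 1:
            return NO_DIRECTION
        return CO_OCCURRENCE if self.odds_ratio > 1 else EXCLUSIVITY

    def swapped(self) -> "PairAssociation":
        """The same association with the two genes exchanged (n10/n01 transpose)."""
        return PairAssociation(
            self.gene_b, self.gene_a, self.n11, self.n01, self.n10, self.n00,
            self.odds_ratio, self.p_value, self.q_value,
        )


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    complete = ~(np.isnan(a) | np.isnan(b))
    a = a[complete]
    b = b[complete]
    n11 = int(np.sum((a == MUT) & (b == MUT)))
    n10 = int(np.sum((a == MUT) & (b == WT)))
    n01 = int(np.sum((a == WT) & (b == MUT)))
    n00 = int(np.sum((a == WT) & (b == WT)))
    return n11, n10, n01, n00


def fisher_pair(m: MutationMatrix, gene_a: str, gene_b: str) -> PairAssociation:
    """Two-sided Fisher exact test for one gene pair over pairwise-complete samples."""
    for g in (gene_a, gene_b):
        if g not in m.status.columns:
            raise ValidationError(f"gene {g!r} not present in the matrix")
    a = m.status[gene_a].to_numpy(dtype="float64", na_value=np.nan)
    b = m.status[gene_b].to_numpy(dtype="float64", na_value=np.nan)
    n11, n10, n01, n00 = _pair_counts(a, b)
    if n11 + n10 + n01 + n00 == 0:
        raise UndefinedPairError(f"no sample assayed for both {gene_a} and {gene_b}")
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return PairAssociation(gene_a, gene_b, n11, n10, n01, n00, sample_odds_ratio(n11, n10, n01, n00), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComutNetwork:
    """Co-mutation network: gene nodes with mutation rates, signed significant edges."""

    node_frequency: pd.Series
    pairs: list[PairAssociation]
    q_threshold: float = 0.05

    @property
    def edges(self) -> list[PairAssociation]:
        return [
            pa
            for pa in self.pairs
            if pa.q_value is not None and pa.q_value < self.q_threshold and pa.direction != NO_DIRECTION
        ]

    def pair_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": pa.gene_a,
                "gene_b": pa.gene_b,
                "n11": pa.n11,
                "n10": pa.n10,
                "n01": pa.n01,
                "n00": pa.n00,
                "odds_ratio": pa.odds_ratio,
                "p_value": pa.p_value,
                "q_value": pa.q_value,
                "direction": pa.direction,
            }
            for pa in self.pairs
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        table = self.pair_table()
        if table.empty:
            return table
        keep = (table["q_value"] < self.q_threshold) & (table["direction"] != NO_DIRECTION)
        return table[keep].reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "q_threshold": self.q_threshold,
            "nodes": [
                {"gene": g, "mutation_frequency": None if pd.isna(f) else float(f)}
                for g, f in self.node_frequency.items()
            ],
            "edges": [
                {
                    "gene_a": pa.gene_a,
                    "gene_b": pa.gene_b,
                    "odds_ratio": pa.odds_ratio,
                    "q_value": pa.q_value,
                    "direction": pa.direction,
                }
                for pa in self.edges
            ],
        }


def all_pairs(m: MutationMatrix, q_threshold: float = 0.05) -> ComutNetwork:
    """Fisher test over all unordered gene pairs with one BH family across them.

    Pairs with no pairwise-complete sample are dropped with a warning rather
    than propagating an error.  Edges require q strictly below the threshold
    and an odds ratio different from 1.
    """
    if m.n_genes < 2:
        raise ValidationError("need at least two genes for pairwise testing")
    pairs: list[PairAssociation] = []
    for gene_a, gene_b in itertools.combinations(m.genes, 2):
        try:
            pairs.append(fisher_pair(m, gene_a, gene_b))
        except UndefinedPairError as exc:
            warnings.warn(str(exc))
    if pairs:
        q = bh_adjust([pa.p_value for pa in pairs])
        for pa, qv in zip(pairs, q):
            pa.q_value = float(qv)
    return ComutNetwork(m.mutation_frequency(), pairs, q_threshold)


# ---------------------------------------------------------------------------
# Set-level indicators and stratified exclusivity
# ---------------------------------------------------------------------------

def set_indicator(m: MutationMatrix, genes) -> pd.Series:
    """Per-sample mutant indicator for a gene set.

    MUT if any member gene is mutant; NA if any member is not assayed and
    none is mutant (wild-type status of the set cannot be asserted); WT
    otherwise.
    """
    genes = list(genes)
    for g in genes:
        if g not in m.status.columns:
            raise ValidationError(f"gene {g!r} not present in the matrix")
    sub = m.status[genes]
    any_mut = sub.eq(MUT).fillna(False).any(axis=1)
    any_na = sub.isna().any(axis=1)
    out = pd.Series(WT, index=m.status.index, dtype="Float64")
    out[any_na] = pd.NA
    out[any_mut] = MUT
    return out.astype("Int8")


def stratified_exclusivity(
    m: MutationMatrix,
    clinical: pd.DataFrame,
    stratum: str,
    set_a,
    set_b,
) -> dict[str, PairAssociation]:
    """Set-level Fisher association within each level of a clinical covariate.

    The two gene sets are collapsed to per-sample indicators; one 2x2 table
    and association is computed per stratum level.  p-values are reported
    raw (no FDR across strata).  Empty or undefined levels are skipped with
    a warning.
    """
    if stratum not in clinical.columns:
        raise ValidationError(f"stratum {stratum!r} not in clinical table")
    ind_a = set_indicator(m, set_a)
    ind_b = set_indicator(m, set_b)
    name_a = "+".join(set_a)
    name_b = "+".join(set_b)
    levels = clinical[stratum].dropna().unique()
    if len(levels) < 2:
        raise ValidationError(f"stratum {stratum!r} has fewer than two levels")
    out: dict[str, PairAssociation] = {}
    for level in levels:
        samples = clinical.index[clinical[stratum] == level]
        samples = [s for s in samples if s in ind_a.index]
        if not samples:
            warnings.warn(f"stratum level {level!r} has no samples in the matrix; skipped")
            continue
        a = ind_a.loc[samples].to_numpy(dtype="float64", na_value=np.nan)
        b = ind_b.loc[samples].to_numpy(dtype="float64", na_value=np.nan)
        n11, n10, n01, n00 = _pair_counts(a, b)
        if n11 + n10 + n01 + n00 == 0:
            warnings.warn(f"stratum level {level!r} has no pairwise-complete samples; skipped")
            continue
        _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        out[str(level)] = PairAssociation(
            name_a, name_b, n11, n10, n01, n00, sample_odds_ratio(n11, n10, n01, n00), float(p)
        )
    return out


# ---------------------------------------------------------------------------
# Utilities for working from printed marginal counts
# ---------------------------------------------------------------------------

def reconstruct_pair_table(n: int, n_a: int, n_b: int, target_or: float) -> tuple[int, int, int, int]:
    """Recover the 2x2 table from a total, two mutant margins and a printed odds ratio.

    Exhaustively scans the feasible co-mutant count and returns the table
    whose sample odds ratio is closest (on the log scale) to ``target_or``.
    Useful when a publication prints margins and the odds ratio but not the
    table itself.
    """
    if not 0 < target_or < math.inf:
        raise ValidationError("target odds ratio must be finite and positive")
    best = None
    best_dist = math.inf
    lo = max(0, n_a + n_b - n)
    hi = min(n_a, n_b)
    for n11 in range(lo, hi + 1):
        n10 = n_a - n11
        n01 = n_b - n11
        n00 = n - n_a - n_b + n11
        oratio = sample_odds_ratio(n11, n10, n01, n00)
        if not 0 < oratio < math.inf:
            continue
        dist = abs(math.log(oratio) - math.log(target_or))
        if dist < best_dist:
            best_dist = dist
            best = (n11, n10, n01, n00)
    if best is None:
        raise ValidationError("no feasible table with a finite positive odds ratio")
    return best


def matrix_from_pair_counts(
    n11: int, n10: int, n01: int, n00: int, gene_a: str = "gene_a", gene_b: str = "gene_b"
) -> MutationMatrix:
    """Build a minimal two-gene :class:`MutationMatrix` realising a 2x2 table."""
    rows = (
        [(MUT, MUT)] * n11 + [(MUT, WT)] * n10 + [(WT, MUT)] * n01 + [(WT, WT)] * n00
    )
    values = np.array(rows, dtype=float)
    samples = [f"S{i + 1:04d}" for i in range(len(rows))]
    return MutationMatrix(_as_status_frame(values, samples, [gene_a, gene_b]))
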