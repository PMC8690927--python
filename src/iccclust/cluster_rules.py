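"""Deterministic seven-gene cluster and sub-cluster assignment, plus TMB comparison.

The clustering system rests on seven recurrent driver events:

* Cluster1 genes: KRAS, TP53, SMAD4 -- any mutation places a sample in C1,
  irrespective of other mutations (so rare double mutants carrying both a
  Cluster1-set and a Cluster2-set mutation stay in C1, flagged ``co_mutant``).
* Cluster2 genes: IDH1, IDH2, FGFR2_fusion, BAP1 -- any mutation, with all
  Cluster1 genes non-mutant, places a sample in C2.
* Cluster3 requires all seven genes assayed and wild-type; a sample with an
  unassayed gene and no observed mutation cannot assert wild-type status and
  is labelled UNCLASSIFIED.

Sub-clusters: within C1, 1A iff KRAS mutant else 1B (TP53/SMAD4 with
wild-type KRAS); within C2, 2A iff IDH1/IDH2 mutant (irrespective of the
rest), else 2B iff FGFR2 fusion, else 2C (BAP1 only).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MUT, WT, MutationMatrix
from .errors import ValidationError

C1_GENES = ("KRAS", "TP53", "SMAD4")
C2_GENES = ("IDH1", "IDH2", "FGFR2_fusion", "BAP1")
SEVEN_GENES = C1_GENES + C2_GENES

CLUSTERS = ("C1", "C2", "C3", "UNCLASSIFIED")
SUBCLUSTERS = ("1A", "1B", "2A", "2B", "2C", "none")


@dataclass(frozen=True)
class ClusterAssignment:
    sample_id: str | None
    cluster: str
    subcluster: str
    co_mutant: bool


def _is_mut(v) -> bool:
    return (not pd.isna(v)) and int(v) == MUT


def _is_wt(v) -> bool:
    return (not pd.isna(v)) and int(v) == WT


def assign_cluster(status: Mapping[str, object], sample_id: str | None = None) -> ClusterAssignment:
    """Assign one sample given its seven-gene states (MUT=1 / WT=0 / NA=missing).

    Genes absent from ``status`` are treated as not assayed.  The function is
    total: every input maps to exactly one cluster label.
    """
    get = lambda g: status.get(g, None)
    c1_mut = any(_is_mut(get(g)) for g in C1_GENES)
    c2_mut = any(_is_mut(get(g)) for g in C2_GENES)
    all_wt = all(_is_wt(get(g)) for g in SEVEN_GENES)
    co_mutant = c1_mut and c2_mut

    if c1_mut:
        cluster = "C1"
        subcluster = "1A" if _is_mut(get("KRAS")) else "1B"
    elif c2_mut:
        cluster = "C2"
        if _is_mut(get("IDH1")) or _is_mut(get("IDH2")):
            subcluster = "2A"
        elif _is_mut(get("FGFR2_fusion")):
            subcluster = "2B"
        else:
            subcluster = "2C"
    elif all_wt:
        cluster, subcluster = "C3", "none"
    else:
        cluster, subcluster = "UNCLASSIFIED", "none"
    return ClusterAssignment(sample_id, cluster, subcluster, co_mutant)


def assign_all(m: MutationMatrix) -> pd.DataFrame:
    """Vectorised cluster assignment for every sample of a matrix.

    Returns a DataFrame indexed by sample with columns ``cluster``,
    ``subcluster`` and ``co_mutant``.
    """
    s = m.status.reindex(columns=list(SEVEN_GENES))
    mut = s.eq(MUT).fillna(False).astype(bool)
    wt = s.eq(WT).fillna(False).astype(bool)

    any_c1 = mut[list(C1_GENES)].any(axis=1)
    any_c2 = mut[list(C2_GENES)].any(axis=1)
    all_wt = wt.all(axis=1)

    cluster = np.select(
        [any_c1, any_c2, all_wt],
        ["C1", "C2", "C3"],
        default="UNCLASSIFIED",
    )
    idh_mut = mut["IDH1"] | mut["IDH2"]
    subcluster = np.select(
        [
            any_c1 & mut["KRAS"],
            any_c1,
            ~any_c1 & any_c2 & idh_mut,
            ~any_c1 & any_c2 & mut["FGFR2_fusion"],
            ~any_c1 & any_c2,
        ],
        ["1A", "1B", "2A", "2B", "2C"],
        default="none",
    )
    return pd.DataFrame(
        {
            "cluster": cluster,
            "subcluster": subcluster,
            "co_mutant": (any_c1 & any_c2).to_numpy(),
        },
        index=m.status.index,
    )


def compare_tmb(
    m: MutationMatrix,
    assignments: pd.DataFrame,
    by: str = "cluster",
    exclude: tuple[str, ...] = ("UNCLASSIFIED", "none"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group tumour mutational burden summaries and pairwise Mann-Whitney tests.

    Groups come from the ``by`` column of ``assignments``; samples without a
    non-synonymous count are ignored and groups left empty are dropped with a
    warning.  Tests are two-sided; exact enumeration when both groups have
    at most 8 observations, tie-corrected normal approximation otherwise.
    """
    if m.nonsyn_count is None:
        raise ValidationError("matrix has no non-synonymous counts")
    if by not in assignments.columns:
        raise ValidationError(f"assignments have no column {by!r}")
    counts = m.nonsyn_count.dropna().astype(int)
    labels = assignments.loc[assignments.index.intersection(counts.index), by]

    groups: dict[str, np.ndarray] = {}
    for label in pd.unique(labels):
        if label in exclude:
            continue
        vals = counts.loc[labels.index[labels == label]].to_numpy()
        if vals.size == 0:
            warnings.warn(f"group {label!r} has no mutation counts; excluded")
            continue
        groups[str(label)] = vals
    if len(groups) < 2:
        raise ValidationError("need at least two groups with counts for TMB comparison")

    summary = pd.DataFrame(
        [
            {
                "group": g,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
            for g, v in groups.items()
        ]
    )
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        x, y = groups[ga], groups[gb]
        method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {"group_a": ga, "group_b": gb, "u_statistic": float(res.statistic), "p_value": float(res.pvalue)}
        )
    return summary, pd.DataFrame(rows)
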