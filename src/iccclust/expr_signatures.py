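"""Gene-signature enrichment scoring, three-group classification and differential expression.

Expression matrices are genes x samples DataFrames on a log2 scale.  A
signature is a named up/down gene list pair (GMT on disk).  The per-sample
enrichment score is the mean across-sample z-score of the up genes minus
that of the down genes -- a deterministic single-sample summary that is
invariant to per-gene location shifts and flips sign when up and down lists
are swapped.

Two signature scores classify samples into three groups (A / B / mixed)
via a score-difference margin; per-gene Welch t-tests and linear fold
changes support intersecting differential genes across datasets into a
consensus signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyOverlapError, ValidationError

MIXED = "mixed"


@dataclass(frozen=True)
class SignatureSet:
    """A named gene signature with up- and (optionally) down-regulated members."""

    name: str
    up: tuple[str, ...] = ()
    down: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", tuple(self.up))
        object.__setattr__(self, "down", tuple(self.down))
        if not self.up and not self.down:
            raise ValidationError(f"signature {self.name!r} is empty")
        if set(self.up) & set(self.down):
            raise ValidationError(f"signature {self.name!r} has overlapping up/down genes")

    def swapped(self) -> "SignatureSet":
        return SignatureSet(self.name, self.down, self.up)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [genes]}`` (description field ignored)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def collapse_duplicates(x: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the highest-variance row per gene."""
    if not x.index.has_duplicates:
        return x
    variances = x.var(axis=1, ddof=1)
    order = np.argsort(-variances.to_numpy(), kind="stable")
    deduped = x.iloc[order][~x.index[order].duplicated()]
    return deduped.loc[x.index.drop_duplicates()]


def zscore_frame(x: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-score across samples; zero-variance genes map to 0."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=ddof)
    z = x.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def enrichment_score(x: pd.DataFrame, sig: SignatureSet) -> pd.Series:
    """Per-sample signature enrichment: mean z of up genes minus mean z of down genes.

    Signature genes absent from the matrix are skipped and reported via a
    warning (and in the result's ``attrs['missing_genes']``); no overlap at
    all raises :class:`EmptyOverlapError`.
    """
    if x.index.has_duplicates:
        raise ValidationError("expression matrix has duplicate gene ids; collapse first")
    up = [g for g in sig.up if g in x.index]
    down = [g for g in sig.down if g in x.index]
    missing = sorted((set(sig.up) | set(sig.down)) - set(x.index))
    if not up and not down:
        raise EmptyOverlapError(f"signature {sig.name!r} shares no genes with the matrix")
    if missing:
        warnings.warn(f"signature {sig.name!r}: {len(missing)} genes absent from the matrix")
    z = zscore_frame(x.loc[up + down])
    score = z.loc[up].mean(axis=0) if up else pd.Series(0.0, index=x.columns)
    if down:
        score = score - z.loc[down].mean(axis=0)
    score.name = sig.name
    score.attrs["missing_genes"] = missing
    return score


def classify_three_group(
    score_a: pd.Series,
    score_b: pd.Series,
    margin: float = 0.2,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.Series:
    """Label samples by which of two signature scores dominates.

    ``label_a`` when score_a - score_b > margin, ``label_b`` for the reverse,
    ``mixed`` otherwise.  Swapping the two scores exchanges the labels.
    """
    score_a, score_b = score_a.align(score_b, join="inner")
    diff = score_a - score_b
    out = pd.Series(MIXED, index=diff.index, dtype=object)
    out[diff > margin] = label_a
    out[-diff > margin] = label_b
    return out


def differential_expression(x1: pd.DataFrame, x2: pd.DataFrame) -> pd.DataFrame:
    """Per-gene linear fold change and Welch t-test between two sample groups.

    Inputs are log2 expression; the fold change is ``2 ** (mean1 - mean2)``
    so direction is signed by the group order.  Genes constant in both
    groups get p = 1 by convention.
    """
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValidationError("each group needs at least two samples")
    common = x1.index.intersection(x2.index)
    if len(common) < len(x1.index) or len(common) < len(x2.index):
        warnings.warn("groups share only a subset of genes; restricting to the intersection")
    if len(common) == 0:
        raise ValidationError("groups share no genes")
    a = x1.loc[common].to_numpy(dtype=float)
    b = x2.loc[common].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log2_fc = mean_a - mean_b
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "fold_change": np.exp2(log2_fc),
            "p_value": p,
        },
        index=common,
    )


def intersect_signature(
    de_results: list[pd.DataFrame],
    fc_min: float = 2.0,
    p_max: float = 0.05,
    top_fc: float = 4.0,
) -> pd.DataFrame:
    """Consensus differential genes across datasets, with a top-discriminator flag.

    A gene enters the consensus when it passes fold change > ``fc_min`` in a
    consistent direction (up in every dataset, or down -- i.e. fold change
    < 1/``fc_min`` -- in every dataset) with p < ``p_max`` in every dataset.
    ``is_top`` marks consensus genes whose cross-dataset average fold-change
    magnitude exceeds ``top_fc``.  An empty consensus is returned empty.
    """
    if len(de_results) < 2:
        raise ValidationError("need at least two datasets to intersect")
    common = de_results[0].index
    for de in de_results[1:]:
        common = common.intersection(de.index)
    fc = np.column_stack([de.loc[common, "fold_change"].to_numpy() for de in de_results])
    p = np.column_stack([de.loc[common, "p_value"].to_numpy() for de in de_results])
    sig = (p < p_max).all(axis=1)
    up = sig & (fc > fc_min).all(axis=1)
    down = sig & (fc < 1.0 / fc_min).all(axis=1)
    magnitude = np.where(fc >= 1, fc, 1.0 / fc).mean(axis=1)
    keep = up | down
    out = pd.DataFrame(
        {
            "direction": np.where(up, "up", "down")[keep],
            "mean_fc_magnitude": magnitude[keep],
            "is_top": (magnitude > top_fc)[keep],
        },
        index=common[keep],
    )
    return out
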