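"""Differential DNA methylation (beta-values) and IDH-like sample classification.

Beta matrices are probes x samples with values in [0, 1].  Differential
probes between IDH1/2-mutant and wild-type tumours are called with a Welch
(unequal-variance) two-sample t-test per probe, Benjamini-Hochberg control
of the false discovery rate at 5%, and an additional effect-size filter of
at least a 20% absolute difference in mean beta between the groups.  Both
the test and the effect filter act on raw beta-values, not M-values.

Samples are classified as "IDH-like" / "non-IDH-like" by nearest-centroid
Pearson correlation over the significant probes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comut_stats import bh_adjust
from .errors import FormatError, UndefinedMetricError, ValidationError

IDH_LIKE = "IDH-like"
NON_IDH_LIKE = "non-IDH-like"


def load_beta(path, max_missing: float = 0.2) -> pd.DataFrame:
    """Read a probe x sample beta-value TSV.

    Values must lie in [0, 1] (missing allowed); probes with more than
    ``max_missing`` fraction of missing entries are dropped at load.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA", ""])
    df = df.apply(pd.to_numeric)
    vals = df.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise FormatError("beta-values must lie in [0, 1]")
    missing_frac = df.isna().mean(axis=1)
    return df.loc[missing_frac <= max_missing]


def differential_probes(
    beta: pd.DataFrame,
    mutant_samples: Sequence[str],
    fdr: float = 0.05,
    delta_min: float = 0.20,
) -> pd.DataFrame:
    """Welch t-test per probe between mutant and wild-type samples.

    Returns a DataFrame indexed by probe with ``delta_beta`` (mutant mean
    minus wild-type mean), ``p_value``, ``q_value`` (BH across all tested
    probes), ``significant`` (q < fdr) and ``retained`` (significant AND
    ``|delta_beta| >= delta_min``).  Swapping the group labels flips the
    sign of ``delta_beta`` and leaves the retained set unchanged.
    """
    mutant = [s for s in mutant_samples]
    unknown = set(mutant) - set(beta.columns)
    if unknown:
        raise ValidationError(f"mutant samples not in matrix: {sorted(unknown)[:5]}")
    wildtype = [s for s in beta.columns if s not in set(mutant)]
    if len(mutant) < 2 or len(wildtype) < 2:
        raise ValidationError("each group needs at least two samples")

    a = beta[mutant].to_numpy(dtype=float)
    b = beta[wildtype].to_numpy(dtype=float)
    delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    significant = q < fdr
    retained = significant & (np.abs(delta) >= delta_min)
    return pd.DataFrame(
        {
            "delta_beta": delta,
            "p_value": p,
            "q_value": q,
            "significant": significant,
            "retained": retained,
        },
        index=beta.index,
    )


def group_centroids(
    beta: pd.DataFrame, mutant_samples: Sequence[str], probes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean beta profiles of the mutant and wild-type groups over selected probes."""
    mutant = list(mutant_samples)
    wildtype = [s for s in beta.columns if s not in set(mutant)]
    sub = beta if probes is None else beta.loc[list(probes)]
    return pd.DataFrame(
        {"mutant": sub[mutant].mean(axis=1), "wildtype": sub[wildtype].mean(axis=1)}
    )


def classify_idh_like(beta: pd.DataFrame, probes: Sequence[str], centroids: pd.DataFrame) -> pd.Series:
    """Nearest-centroid (Pearson) classification over the significant probes.

    A sample whose significant-probe vector correlates more strongly with
    the mutant centroid than the wild-type centroid is "IDH-like"; exact
    ties go to "non-IDH-like".  Zero-variance sample vectors make the
    correlation undefined and raise.
    """
    probes = list(probes)
    if not probes:
        raise ValidationError("need at least one significant probe")
    sub = beta.loc[probes]
    c_mut = centroids.loc[probes, "mutant"].to_numpy(dtype=float)
    c_wt = centroids.loc[probes, "wildtype"].to_numpy(dtype=float)
    labels = {}
    for sample in sub.columns:
        v = sub[sample].to_numpy(dtype=float)
        ok = ~(np.isnan(v) | np.isnan(c_mut) | np.isnan(c_wt))
        if ok.sum() < 2 or np.std(v[ok]) == 0:
            raise UndefinedMetricError(f"sample {sample!r} has a degenerate probe vector")
        r_mut = np.corrcoef(v[ok], c_mut[ok])[0, 1]
        r_wt = np.corrcoef(v[ok], c_wt[ok])[0, 1]
        labels[sample] = IDH_LIKE if r_mut > r_wt else NON_IDH_LIKE
    return pd.Series(labels, name="idh_like")
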