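"""Reading, writing and filtering of somatic mutation matrices and clinical tables.

The central container is :class:`MutationMatrix`: a samples x genes ternary
status table (mutant / wild-type / not assayed) with optional per-sample
non-synonymous mutation counts.  Statuses are stored as a nullable ``Int8``
DataFrame with 1 = mutant, 0 = wild-type and ``<NA>`` = not assayed.  The
"not assayed" state is first-class because multi-cohort mutation tables mix
whole-exome samples with targeted panels that did not cover every gene (gene
fusions in particular), and all downstream pair statistics must use
pairwise-complete denominators.

Cohort-level filters implemented here:

* hypermutator exclusion -- samples with more than 300 non-synonymous
  mutations are removed (samples without a count, i.e. targeted panels,
  pass through);
* gene inclusion -- a gene is kept when it was assayed in at least 70% of
  samples and mutated in strictly more than 2% of the assayed samples.

The pipeline applies the two filters in a fixed order: hypermutators first,
then gene inclusion, so gene frequencies are computed on the cleaned cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Status codes inside :attr:`MutationMatrix.status`.
MUT = 1
WT = 0

#: MAF variant classifications that count as non-synonymous coding events.
#: Fusions do not appear here; they enter only through the ``FGFR2_fusion``
#: pseudo-gene column of the status matrix.
DEFAULT_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Legacy/alias gene symbols normalised at read time.  Unrecognised symbols
#: are kept verbatim.  The fusion pseudo-gene is deliberately kept distinct
#: from FGFR2 point mutations.
GENE_ALIASES: dict[str, str] = {
    "MLL": "KMT2A",
    "MLL2": "KMT2D",
    "MLL3": "KMT2C",
    "MLL4": "KMT2B",
    "C11ORF30": "EMSY",
    "FAM123B": "AMER1",
    "MYCL1": "MYCL",
    "FGFR2-FUS": "FGFR2_fusion",
    "FGFR2_FUS": "FGFR2_fusion",
    "FGFR2-FUSION": "FGFR2_fusion",
    "FGFR2_FUSION": "FGFR2_fusion",
}

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def normalize_gene(symbol: str) -> str:
    """Map a gene symbol through the alias table; unknown symbols pass verbatim."""
    s = str(symbol).strip()
    return GENE_ALIASES.get(s.upper(), s)


def _as_status_frame(values, samples, genes) -> pd.DataFrame:
    df = pd.DataFrame(values, index=list(samples), columns=list(genes))
    return df.astype("Float64").astype("Int8")


@dataclass
class MutationMatrix:
    """Ternary sample x gene mutation status plus optional non-synonymous counts.

    Parameters
    ----------
    status:
        samples x genes DataFrame; entries 1 (mutant), 0 (wild-type) or
        ``<NA>`` (gene not assayed for that sample).
    nonsyn_count:
        Per-sample non-synonymous mutation count (nullable integer).  Missing
        counts are permitted only for targeted-panel samples, which are exempt
        from the hypermutator filter.
    """

    status: pd.DataFrame
    nonsyn_count: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.status.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in status matrix")
        if self.status.columns.has_duplicates:
            raise ValidationError("duplicate gene identifiers in status matrix")
        try:
            self.status = self.status.astype("Float64").astype("Int8")
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"status entries must be 0, 1 or NA: {exc}") from exc
        arr = self.status.to_numpy(dtype="float64", na_value=np.nan)
        bad = ~(np.isnan(arr) | (arr == MUT) | (arr == WT))
        if bad.any():
            raise ValidationError("status entries must be 0, 1 or NA")
        # canonical axis labels so write/read round-trips compare equal
        self.status.index.name = None
        self.status.columns.name = None
        if self.nonsyn_count is not None:
            counts = pd.Series(self.nonsyn_count).astype("Float64")
            counts = counts.reindex(self.status.index)
            if (counts.dropna() < 0).any():
                raise ValidationError("nonsyn_count must be non-negative")
            self.nonsyn_count = counts.astype("Int64")

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.status.index)

    @property
    def genes(self) -> list[str]:
        return list(self.status.columns)

    @property
    def n_samples(self) -> int:
        return self.status.shape[0]

    @property
    def n_genes(self) -> int:
        return self.status.shape[1]

    def status_array(self) -> np.ndarray:
        """Status as a float array with NaN for not-assayed entries."""
        return self.status.to_numpy(dtype="float64", na_value=np.nan)

    def assay_coverage(self) -> pd.Series:
        """Fraction of samples assayed, per gene."""
        return self.status.notna().sum(axis=0) / float(self.n_samples)

    def mutation_frequency(self) -> pd.Series:
        """Mutant fraction among assayed samples, per gene (NaN if never assayed)."""
        arr = self.status_array()
        assayed = (~np.isnan(arr)).sum(axis=0).astype(float)
        mut = np.nansum(arr == MUT, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(assayed > 0, mut / assayed, np.nan)
        return pd.Series(freq, index=self.status.columns)

    def subset(self, samples: Iterable[str] | None = None, genes: Iterable[str] | None = None) -> "MutationMatrix":
        status = self.status
        if samples is not None:
            status = status.loc[list(samples)]
        if genes is not None:
            status = status[list(genes)]
        counts = None
        if self.nonsyn_count is not None:
            counts = self.nonsyn_count.loc[status.index]
        return MutationMatrix(status.copy(), counts)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_manifest(path) -> dict[str, list[str]]:
    """Read a panel manifest TSV with columns ``sample_id`` and ``gene``.

    Returns an ordered ``{sample_id: [genes]}`` mapping.  Gene symbols are
    alias-normalised.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"sample_id", "gene"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest is missing columns: {sorted(missing)}")
    manifest: dict[str, list[str]] = {}
    for sample, gene in zip(df["sample_id"], df["gene"]):
        manifest.setdefault(sample, [])
        g = normalize_gene(gene)
        if g not in manifest[sample]:
            manifest[sample].append(g)
    return manifest


def read_maf(
    path,
    variant_classes: Iterable[str] = DEFAULT_VARIANT_CLASSES,
    manifest: Mapping[str, Iterable[str]] | str | Path | None = None,
) -> MutationMatrix:
    """Build a :class:`MutationMatrix` from a MAF-style mutation table.

    A sample carries MUT for a gene iff at least one qualifying record exists.
    Genes in a sample's panel manifest with no qualifying record are WT; genes
    outside the manifest are not-assayed and any records for them are ignored
    with a warning.  ``nonsyn_count`` is the number of qualifying records per
    sample after de-duplication.

    Without a manifest every observed sample is assumed fully assayed for the
    union of observed genes (the whole-exome/-genome convention).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", low_memory=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"MAF is missing mandatory columns: {missing}")

    variant_classes = set(variant_classes)
    df = df.assign(_gene=df["Hugo_Symbol"].map(normalize_gene))
    qual = df[df["Variant_Classification"].isin(variant_classes)].copy()

    dedup_keys = ["Tumor_Sample_Barcode", "_gene", "Variant_Classification"]
    dedup_keys += [c for c in ("HGVSp_Short", "Protein_Change", "Start_Position") if c in qual.columns]
    n_before = len(qual)
    qual = qual.drop_duplicates(subset=dedup_keys)
    if len(qual) < n_before:
        warnings.warn(f"dropped {n_before - len(qual)} duplicate (sample, gene, variant) records")

    if manifest is None:
        samples = list(dict.fromkeys(df["Tumor_Sample_Barcode"]))
        genes = list(dict.fromkeys(qual["_gene"]))
        manifest_map = {s: genes for s in samples}
    else:
        if not isinstance(manifest, Mapping):
            manifest_map = read_manifest(manifest)
        else:
            manifest_map = {s: [normalize_gene(g) for g in gs] for s, gs in manifest.items()}
        samples = list(manifest_map)
        genes = list(dict.fromkeys(g for gs in manifest_map.values() for g in gs))
        unknown = set(qual["Tumor_Sample_Barcode"]) - set(samples)
        if unknown:
            warnings.warn(f"ignoring records for {len(unknown)} samples absent from the manifest")
            qual = qual[qual["Tumor_Sample_Barcode"].isin(samples)]

    values = np.full((len(samples), len(genes)), np.nan)
    gene_pos = {g: j for j, g in enumerate(genes)}
    sample_pos = {s: i for i, s in enumerate(samples)}
    for s in samples:
        covered = manifest_map.get(s, ())
        for g in covered:
            values[sample_pos[s], gene_pos[g]] = WT

    counts = pd.Series(0, index=samples, dtype="int64")
    n_outside = 0
    for s, g in zip(qual["Tumor_Sample_Barcode"], qual["_gene"]):
        j = gene_pos.get(g)
        if j is None or np.isnan(values[sample_pos[s], j]):
            n_outside += 1
            continue
        values[sample_pos[s], j] = MUT
        counts[s] += 1
    if n_outside:
        warnings.warn(f"ignored {n_outside} records for genes outside the sample's panel manifest")

    return MutationMatrix(_as_status_frame(values, samples, genes), counts)


def read_matrix(status_path, counts_path=None) -> MutationMatrix:
    """Read a sample x gene status TSV (cells 1 / 0 / NA) and optional counts TSV."""
    df = pd.read_csv(status_path, sep="\t", index_col=0, comment="#", na_values=["NA", ""])
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"status matrix has non-numeric cells: {exc}") from exc
    counts = None
    if counts_path is not None:
        cdf = pd.read_csv(counts_path, sep="\t", comment="#", na_values=["NA", ""])
        if not {"sample_id", "nonsyn_count"} <= set(cdf.columns):
            raise FormatError("counts file needs columns sample_id and nonsyn_count")
        counts = pd.Series(cdf["nonsyn_count"].values, index=cdf["sample_id"].astype(str).values)
    return MutationMatrix(df, counts)


def _write_commented(frame: pd.DataFrame, path, header: str | None, **to_csv_kwargs) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", na_rep="NA", **to_csv_kwargs)


def write_matrix(m: MutationMatrix, status_path, counts_path=None, header: str | None = None) -> None:
    """Write the ternary matrix (and optionally the counts) as TSV.

    ``header`` lines, if given, are prepended as ``#``-comments so
    :func:`read_matrix` round-trips the matrix exactly.
    """
    _write_commented(m.status, status_path, header, index_label="sample_id")
    if counts_path is not None:
        if m.nonsyn_count is None:
            raise ValidationError("matrix has no nonsyn counts to write")
        counts = m.nonsyn_count.rename("nonsyn_count").rename_axis("sample_id").reset_index()
        _write_commented(counts, counts_path, header, index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

_CLINICAL_NUMERIC = ("age", "ca19_9", "os_months", "os_event", "rfs_months", "rfs_event")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical covariate TSV indexed by ``sample_id``.

    Numeric columns are coerced; survival times must be non-negative and
    event flags binary.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", ""])
    if "sample_id" not in df.columns:
        raise FormatError("clinical table needs a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    for col in _CLINICAL_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("os_months", "rfs_months"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"{col} contains negative times")
    for col in ("os_event", "rfs_event"):
        if col in df.columns and not df[col].dropna().isin([0, 1]).all():
            raise ValidationError(f"{col} must be 0/1")
    return df


_STAGE_LOW = {"I", "II", "1", "2", "IA", "IB", "IIA", "IIB"}
_STAGE_HIGH = {"III", "IV", "3", "4", "IIIA", "IIIB", "IVA", "IVB"}


def dichotomize_stage(stage) -> pd.Series:
    """Deterministically collapse AJCC stage to ``I/II`` vs ``III/IV``."""
    s = pd.Series(stage).astype("string").str.strip().str.upper()
    out = pd.Series(pd.NA, index=s.index, dtype="string")
    out[s.isin(_STAGE_LOW)] = "I/II"
    out[s.isin(_STAGE_HIGH)] = "III/IV"
    return out


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def filter_hypermutators(m: MutationMatrix, max_nonsyn: int = 300) -> MutationMatrix:
    """Drop samples whose non-synonymous count strictly exceeds ``max_nonsyn``.

    Samples without a count (targeted panels) pass through: the rule only
    applies where the count is defined.
    """
    if m.nonsyn_count is None:
        return m
    counts = m.nonsyn_count
    keep = [s for s in m.samples if pd.isna(counts[s]) or counts[s] <= max_nonsyn]
    return m.subset(samples=keep)


def filter_genes(m: MutationMatrix, coverage_min: float = 0.70, freq_min: float = 0.02) -> MutationMatrix:
    """Keep genes assayed in >= ``coverage_min`` of samples and mutated in > ``freq_min`` of assayed samples.

    The coverage bound is inclusive, the frequency bound strict, matching the
    cohort-inclusion rule "assayed in at least 70% of samples with mutation
    frequency > 2%".
    """
    if m.n_samples == 0 or m.n_genes == 0:
        raise ValidationError("cannot filter an empty mutation matrix")
    coverage = m.assay_coverage()
    freq = m.mutation_frequency()
    keep = [
        g
        for g in m.genes
        if coverage[g] >= coverage_min and not pd.isna(freq[g]) and freq[g] > freq_min
    ]
    return m.subset(genes=keep)


def apply_cohort_filters(
    m: MutationMatrix,
    max_nonsyn: int = 300,
    coverage_min: float = 0.70,
    freq_min: float = 0.02,
) -> MutationMatrix:
    """Fixed-order cohort cleaning: hypermutator exclusion, then gene inclusion."""
    return filter_genes(filter_hypermutators(m, max_nonsyn), coverage_min, freq_min)
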