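"""End-to-end pipeline: ingest -> filters -> pair statistics -> cluster rules ->
CP score -> expression signatures -> methylation -> survival.

Stages run in a fixed order over pure dataflow (no stage mutates another's
inputs); each output file carries a provenance header with the config hash
and seed.  Stages whose inputs are absent are skipped with an explicit
notice in the summary, so a mutation-only run still produces the pair
statistics and cluster assignments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_rules, comut_stats, cp_score, expr_signatures, methyl_diff, survival_stats
from .cluster_rules import SEVEN_GENES
from .cohort_io import (
    MutationMatrix,
    apply_cohort_filters,
    dichotomize_stage,
    read_clinical,
    read_matrix,
    write_matrix,
)
from .errors import IccclustError, ValidationError

logger = logging.getLogger("iccclust")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    matrix: str | None = None
    counts: str | None = None
    clinical: str | None = None
    expression: str | None = None
    beta: str | None = None
    signatures: str | None = None  # GMT path
    signature_a: str = "poor_prognosis"
    signature_b: str = "good_prognosis"

    coverage_min: float = 0.70
    freq_min: float = 0.02
    max_nonsyn: int = 300
    q_threshold: float = 0.05
    ca199_cutoff: float = 100.0
    margin: float = 0.2
    fdr: float = 0.05
    delta_min: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage_min", "freq_min", "q_threshold", "ca199_cutoff", "margin", "fdr", "delta_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_nonsyn <= 0:
            raise ValidationError("max_nonsyn must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def provenance_header(config: RunConfig) -> str:
    return f"iccclust_config_sha256={config.config_hash()}\nseed={config.seed}"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, index_label=None) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(config).split("\n"):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index_label is not None, index_label=index_label)


class StageError(IccclustError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages for which inputs are available; write the output bundle.

    Returns a summary dict (also written to ``summary.json``) listing stage
    status, key counts and the provenance hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str):
        def wrap(fn):
            try:
                result = fn()
                summary["stages"][name] = {"status": "ok", **(result or {})}
            except IccclustError as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            except FileNotFoundError as exc:
                raise StageError(f"stage {name!r} failed: missing input {exc}") from exc
        return wrap

    def skip(name: str, reason: str) -> None:
        logger.info("skipping stage %s: %s", name, reason)
        summary["stages"][name] = {"status": "skipped", "reason": reason}

    # --- ingest -------------------------------------------------------------
    if config.matrix is None:
        raise StageError("stage 'ingest' failed: no mutation matrix configured")
    matrix = read_matrix(config.matrix, config.counts)
    clinical = read_clinical(config.clinical) if config.clinical else None
    summary["stages"]["ingest"] = {
        "status": "ok",
        "n_samples": matrix.n_samples,
        "n_genes": matrix.n_genes,
        "clinical": clinical is not None,
    }

    # --- cohort filters (fixed order: hypermutators, then genes) ------------
    filtered = apply_cohort_filters(matrix, config.max_nonsyn, config.coverage_min, config.freq_min)
    write_matrix(filtered, out / "filtered_matrix.tsv", header=provenance_header(config))
    summary["stages"]["filters"] = {
        "status": "ok",
        "n_samples": filtered.n_samples,
        "n_genes": filtered.n_genes,
    }

    # --- pairwise statistics -------------------------------------------------
    @stage("comut")
    def _comut():
        network = comut_stats.all_pairs(filtered, config.q_threshold)
        _write_table(network.pair_table(), out / "pair_stats.tsv", config)
        with open(out / "network.json", "w") as fh:
            json.dump({"provenance": provenance_header(config), **network.to_dict()}, fh, indent=1)
        return {"n_pairs": len(network.pairs), "n_edges": len(network.edges)}

    # --- cluster rules -------------------------------------------------------
    assignments = cluster_rules.assign_all(filtered if set(SEVEN_GENES) <= set(filtered.genes) else matrix)
    _write_table(assignments, out / "assignments.tsv", config, index_label="sample_id")
    summary["stages"]["assign"] = {
        "status": "ok",
        "cluster_sizes": assignments["cluster"].value_counts().to_dict(),
    }

    if matrix.nonsyn_count is not None and matrix.nonsyn_count.notna().sum() > 0:
        @stage("tmb")
        def _tmb():
            tmb_summary, tmb_tests = cluster_rules.compare_tmb(matrix, assignments, by="subcluster")
            _write_table(tmb_summary, out / "tmb_summary.tsv", config)
            _write_table(tmb_tests, out / "tmb_tests.tsv", config)
            return {"n_groups": len(tmb_summary)}
    else:
        skip("tmb", "no non-synonymous counts")

    # --- CP score ------------------------------------------------------------
    if clinical is not None and {"s100p", "krt17", "ca19_9"} <= set(clinical.columns):
        @stage("cpscore")
        def _cp():
            cp = cp_score.cp_table(clinical, ca199_cutoff=config.ca199_cutoff)
            cp["modified_cluster"] = cp_score.modified_clustering(assignments, cp)
            _write_table(cp, out / "cp_scores.tsv", config, index_label="sample_id")
            return {"n_scored": int(cp["cp_score"].notna().sum())}
    else:
        skip("cpscore", "clinical table with S100P/KRT17/CA19-9 not provided")

    # --- expression signatures ----------------------------------------------
    if config.expression and config.signatures:
        @stage("signatures")
        def _signatures():
            x = pd.read_csv(config.expression, sep="\t", index_col=0, comment="#")
            x = expr_signatures.collapse_duplicates(x)
            gmt = expr_signatures.read_gmt(config.signatures)
            for name in (config.signature_a, config.signature_b):
                if name not in gmt:
                    raise ValidationError(f"signature {name!r} not in GMT")
            sig_a = expr_signatures.SignatureSet(config.signature_a, up=tuple(gmt[config.signature_a]))
            sig_b = expr_signatures.SignatureSet(config.signature_b, up=tuple(gmt[config.signature_b]))
            score_a = expr_signatures.enrichment_score(x, sig_a)
            score_b = expr_signatures.enrichment_score(x, sig_b)
            labels = expr_signatures.classify_three_group(
                score_a, score_b, config.margin, label_a=sig_a.name, label_b=sig_b.name
            )
            frame = pd.DataFrame({sig_a.name: score_a, sig_b.name: score_b, "label": labels})
            _write_table(frame, out / "signature_scores.tsv", config, index_label="sample_id")
            return {"label_counts": labels.value_counts().to_dict()}
    else:
        skip("signatures", "expression matrix or GMT not provided")

    # --- methylation ----------------------------------------------------------
    if config.beta:
        @stage("methyl")
        def _methyl():
            beta = methyl_diff.load_beta(config.beta)
            idh = comut_stats.set_indicator(matrix, [g for g in ("IDH1", "IDH2") if g in matrix.genes])
            mutant = [s for s in beta.columns if s in idh.index and idh[s] == 1]
            wildtype = [s for s in beta.columns if s in idh.index and idh[s] == 0]
            if len(mutant) < 2 or len(wildtype) < 2:
                raise ValidationError("fewer than two IDH-mutant or wild-type samples with methylation")
            probes = methyl_diff.differential_probes(
                beta[mutant + wildtype], mutant, fdr=config.fdr, delta_min=config.delta_min
            )
            _write_table(probes, out / "methyl_probes.tsv", config, index_label="probe_id")
            retained = list(probes.index[probes["retained"]])
            result = {"n_retained": len(retained)}
            if retained:
                centroids = methyl_diff.group_centroids(beta[mutant + wildtype], mutant, retained)
                labels = methyl_diff.classify_idh_like(beta, retained, centroids)
                _write_table(labels.to_frame(), out / "methyl_labels.tsv", config, index_label="sample_id")
                result["n_idh_like"] = int((labels == methyl_diff.IDH_LIKE).sum())
            return result
    else:
        skip("methyl", "beta matrix not provided")

    # --- survival --------------------------------------------------------------
    if clinical is not None and {"os_months", "os_event"} <= set(clinical.columns):
        @stage("survival")
        def _survival():
            df = clinical.join(assignments, how="inner")
            df = df[df["cluster"].isin(["C1", "C2", "C3"])].dropna(subset=["os_months", "os_event"])
            curves = []
            for level, (curve, median) in survival_stats.km_by_group(
                df, "os_months", "os_event", "cluster"
            ).items():
                curve = curve.assign(cluster=level, median=median)
                curves.append(curve)
            _write_table(pd.concat(curves, ignore_index=True), out / "km_curves.tsv", config)
            lr = survival_stats.logrank(df["os_months"], df["os_event"], df["cluster"])
            with open(out / "logrank.json", "w") as fh:
                json.dump(
                    {
                        "provenance": provenance_header(config),
                        "statistic": lr.statistic,
                        "p_value": lr.p_value,
                        "df": lr.df,
                    },
                    fh,
                    indent=1,
                )
            cox_df = pd.DataFrame(
                {
                    "time": df["os_months"],
                    "event": df["os_event"],
                    "cluster1": (df["cluster"] == "C1").astype(int),
                }
            )
            if "stage" in df.columns:
                cox_df["stage_34"] = (dichotomize_stage(df["stage"]) == "III/IV").astype(int)
            if "ca19_9" in df.columns:
                cox_df["ca199_high"] = (df["ca19_9"] >= config.ca199_cutoff).astype(int)
            cox = survival_stats.cox_fit(cox_df, "time", "event")
            _write_table(cox, out / "cox.tsv", config)
            return {"logrank_p": lr.p_value, "n": int(len(df))}
    else:
        skip("survival", "clinical table with OS not provided")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
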