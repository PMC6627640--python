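"""End-to-end orchestration of the synthetic resistance-signature analysis.

One call runs: simulate cell-line counts → per-clone differential
expression → per-clone GSEA → keyword-filtered top-k set selection →
consensus signature → cell-line Z-score clustering → synthetic cohort
scoring → median-split Kaplan–Meier / log-rank / hazard ratio.  Every
intermediate result is serialized to the standard formats so each stage is
independently re-runnable, and a manifest records the config hash, seed and
SHA-256 of every numeric output: re-running the same config reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    ExpressionMatrix,
    read_clinical_tsv,
    read_expression_tsv,
    read_gmt,
    write_clinical_tsv,
    write_expression_tsv,
    write_gmt,
)
from .diffexpr import de_genes, logcpm, moderated_t_test
from .gsea import EnrichmentResult, GseaParams, run_gsea
from .signature import (
    DEFAULT_SIGNATURE_TOKENS,
    Signature,
    build_consensus_signature,
    read_signature_txt,
    select_topk_polycomb_sets,
    signature_sum_z,
    two_group_separation,
    upgma_cluster,
    write_signature_txt,
    zscore_by_gene,
)
from .survival import logrank_test, median_split, score_group_comparison
from .synthetic_data import (
    CellLineSimConfig,
    CohortSimConfig,
    CollectionSimConfig,
    generate_cellline_experiment,
    generate_geneset_collection,
    generate_patient_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_full", "report_de_counts"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full-run configuration: generator configs plus every stage parameter."""

    cellline: CellLineSimConfig = field(default_factory=CellLineSimConfig)
    collection: CollectionSimConfig = field(default_factory=CollectionSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    gsea: GseaParams = field(default_factory=GseaParams)
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    keyword_tokens: tuple[str, ...] = DEFAULT_SIGNATURE_TOKENS
    top_k_sets: int = 20
    min_lines: int = 4
    seed: int = 0
    out_dir: str = "polysig_run"
    strict_io: bool = False

    def __post_init__(self) -> None:
        # one master seed fans out to every stochastic component
        self.cellline.seed = self.seed
        self.collection.seed = self.seed + 1
        self.cohort.seed = self.seed + 2
        self.gsea.seed = self.seed + 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name, sub_cls in (
            ("cellline", CellLineSimConfig),
            ("collection", CollectionSimConfig),
            ("cohort", CohortSimConfig),
            ("gsea", GseaParams),
        ):
            if name in raw:
                sub = raw.pop(name)
                for key in ("clones_per_parental", "set_size_range", "keyword_tokens"):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[name] = sub_cls(**sub)
        if "keyword_tokens" in raw and isinstance(raw["keyword_tokens"], list):
            raw["keyword_tokens"] = tuple(raw["keyword_tokens"])
        kwargs.update(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class PipelineResult:
    """In-memory handles to everything a full run produced."""

    out_dir: Path
    signature: Signature
    per_line_gsea: dict[str, list[EnrichmentResult]]
    de_counts: pd.DataFrame
    cellline_purity: float
    survival: dict
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _line_averaged(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns (named LINE_repN) into one column per line."""
    owners = [c.rsplit("_rep", 1)[0] for c in matrix.sample_ids]
    df = matrix.data.T.groupby(owners, sort=False).mean().T
    return ExpressionMatrix(df, matrix.value_kind)


def report_de_counts(
    de_results: dict, fc_threshold: float = 2.0, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Per-line counts of up/down differential genes at the given cut-offs."""
    rows = []
    for line, result in de_results.items():
        up, down = de_genes(result, fc_threshold, fdr_threshold)
        rows.append({"line": line, "n_up": len(up), "n_down": len(down)})
    return pd.DataFrame(rows, columns=["line", "n_up", "n_down"])


def run_full(config: PipelineConfig) -> PipelineResult:
    """Run the entire synthetic analysis and write a reproducible run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "de").mkdir(exist_ok=True)
    (out / "gsea").mkdir(exist_ok=True)

    logger.info(
        "thresholds: FDR<%s, fold-change>%s, GSEA sizes [%s, %s], %s permutations, "
        "top %s keyword sets per line, signature occurrence >= %s lines, median split",
        config.fdr_threshold,
        config.fc_threshold,
        config.gsea.min_size,
        config.gsea.max_size,
        config.gsea.n_perm,
        config.top_k_sets,
        config.min_lines,
    )

    # --- simulate -----------------------------------------------------------
    try:
        counts, designs, truth = generate_cellline_experiment(config.cellline)
        collection, truth = generate_geneset_collection(config.collection, truth)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    counts_path = write_expression_tsv(counts, out / "counts.tsv")
    gmt_path = write_gmt(collection, out / "collection.gmt")
    if config.strict_io:
        counts = read_expression_tsv(counts_path)
        collection = read_gmt(gmt_path)

    # --- per-line DE and GSEA ----------------------------------------------
    try:
        log_matrix = logcpm(counts)
    except Exception as exc:
        raise PipelineError("logcpm", str(exc)) from exc

    de_results = {}
    gsea_results: dict[str, list[EnrichmentResult]] = {}
    for clone, design in designs.items():
        try:
            de_results[clone] = moderated_t_test(log_matrix, design)
        except Exception as exc:
            raise PipelineError("diffexpr", f"line {clone}: {exc}") from exc
        de_results[clone].table.to_csv(
            out / "de" / f"{clone}.tsv", sep="\t", float_format="%.10g"
        )
        try:
            gsea_results[clone] = run_gsea(log_matrix, design, collection, config.gsea)
        except Exception as exc:
            raise PipelineError("gsea", f"line {clone}: {exc}") from exc
        _write_gsea_tsv(gsea_results[clone], out / "gsea" / f"{clone}.tsv")

    de_counts = report_de_counts(de_results, config.fc_threshold, config.fdr_threshold)
    de_counts.to_csv(out / "de_counts.tsv", sep="\t", index=False)

    # --- consensus signature ------------------------------------------------
    per_line_edges = {}
    provenance = {}
    for clone, results in gsea_results.items():
        top = select_topk_polycomb_sets(results, config.keyword_tokens, config.top_k_sets)
        edges: set[str] = set()
        for r in top:
            edges.update(r.leading_edge)
        per_line_edges[clone] = edges
        provenance[clone] = [r.set_name for r in top]
    try:
        signature = build_consensus_signature(
            per_line_edges, min_lines=config.min_lines, provenance=provenance
        )
    except Exception as exc:
        raise PipelineError("signature", str(exc)) from exc
    sig_path = write_signature_txt(signature, out / "signature.txt")
    if config.strict_io:
        signature = read_signature_txt(sig_path, min_lines=config.min_lines)
    if len(signature) == 0:
        raise PipelineError(
            "scoring",
            f"consensus signature is empty at min_lines={config.min_lines}; "
            "nothing to score",
        )

    # --- cell-line clustering and scores ------------------------------------
    try:
        line_means = _line_averaged(log_matrix)
        # the clustered panel: parental lines plus the profiled clones
        parental = {d.reference_group for d in designs.values()}
        panel = [
            c for c in line_means.sample_ids if c in parental or c in designs
        ]
        line_means = line_means.subset_samples(panel)
        zlines, _ = zscore_by_gene(line_means)
        present = [g for g in signature.genes if g in zlines.data.index]
        zsig = zlines.subset_genes(present)
        dendro = upgma_cluster(zsig)
        labels = {
            line: ("resistant" if line in designs else "parental")
            for line in line_means.sample_ids
        }
        purity = two_group_separation(dendro, labels)
        line_scores = signature_sum_z(zlines, signature)
    except Exception as exc:
        raise PipelineError("clustering", str(exc)) from exc

    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "sum_z": s.sum_z, "n_genes_used": s.n_genes_used}
            for s in line_scores
        ]
    ).to_csv(out / "cellline_scores.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out / "dendrogram.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "leaves": dendro.leaves,
                "merges": [[a, b, float(f"{h:.10g}")] for a, b, h in dendro.merges],
                "two_group_purity": purity,
            },
            fh,
            indent=1,
        )

    # --- cohort scoring and survival ----------------------------------------
    try:
        cohort_expr, records, cohort_truth = generate_patient_cohort(
            config.cohort, signature.genes
        )
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    expr_path = write_expression_tsv(cohort_expr, out / "cohort_expression.tsv")
    clin_path = write_clinical_tsv(records, out / "cohort_clinical.tsv")
    if config.strict_io:
        cohort_expr = read_expression_tsv(expr_path)
        records, _ = read_clinical_tsv(clin_path)

    try:
        zcohort, _ = zscore_by_gene(cohort_expr)
        scores = signature_sum_z(zcohort, signature)
        groups = median_split(scores)
        by_id = {r.sample_id: r for r in records}
        low = [by_id[s] for s, g in groups.items() if g == "low"]
        high = [by_id[s] for s, g in groups.items() if g == "high"]
        comparison = logrank_test(high, low)
        status = {
            r.sample_id: ("recurred" if r.event == 1 else "disease-free") for r in records
        }
        score_diff, score_p = score_group_comparison(scores, status)
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc

    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "sum_z": s.sum_z,
                "n_genes_used": s.n_genes_used,
                "group": groups[s.sample_id],
            }
            for s in scores
        ]
    ).to_csv(out / "cohort_scores.tsv", sep="\t", index=False, float_format="%.10g")

    survival_summary = {
        "chi2": _round(comparison.chi2),
        "p": _round(comparison.p),
        "hazard_ratio": _round(comparison.hr),
        "hazard_ratio_ci": [_round(x) for x in comparison.hr_ci],
        "observed_events": {"high": comparison.o1, "low": comparison.o2},
        "expected_events": {"high": _round(comparison.e1), "low": _round(comparison.e2)},
        "n_events": int(sum(r.event for r in records)),
        "score_diff_recurred_minus_disease_free": _round(score_diff),
        "score_comparison_p": _round(score_p),
        "km": {
            name: {
                "event_times": km.event_times,
                "survival": [_round(v) for v in km.survival],
                "at_risk": km.at_risk,
                "events": km.events,
            }
            for name, km in (("high", comparison.km1), ("low", comparison.km2))
        },
    }
    with open(out / "survival.json", "w", encoding="utf-8") as fh:
        json.dump(survival_summary, fh, indent=1)

    # --- manifest ------------------------------------------------------------
    numeric_outputs = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.suffix in {".tsv", ".gmt", ".txt", ".json"}
        and p.name != "manifest.json"
    )
    manifest = {
        "polysig_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_gsea_runs": len(gsea_results),
        "n_signature_genes": len(signature),
        "outputs": {rel: _sha256(out / rel) for rel in numeric_outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)

    return PipelineResult(
        out_dir=out,
        signature=signature,
        per_line_gsea=gsea_results,
        de_counts=de_counts,
        cellline_purity=purity,
        survival=survival_summary,
        manifest=manifest,
    )


def _round(x: float, digits: int = 10) -> float:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    return float(f"{x:.{digits}g}")


def _write_gsea_tsv(results: list[EnrichmentResult], path: Path) -> None:
    rows = [
        {
            "set": r.set_name,
            "size": r.size_after_filter,
            "es": r.es,
            "nes": r.nes,
            "p": r.p_perm,
            "q": r.q,
            "leading_edge": ",".join(r.leading_edge),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "q", "leading_edge"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
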