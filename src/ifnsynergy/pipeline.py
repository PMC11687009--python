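"""End-to-end pipeline orchestration with reproducible run manifests.

Two entry pipelines chain the library stages on synthetic or user data:

* :func:`run_factorial_pipeline` — size factors -> dispersion -> two-factor
  NB fits with interaction LRT -> response-gene filter -> non-additive
  classification -> overlap enrichment of the non-additive set against the
  planted-class (or user) gene sets.
* :func:`run_cohort_pipeline` — wild-type filter -> TPM filter ->
  log2(TPM+1) -> response scores -> MITF halves/quartiles and PD-L1 splits
  -> association statistics -> PCA -> ranked gene-set enrichment with
  leading edges and core genes.

Every run writes its intermediates as files plus a ``manifest.json``
recording the configuration, seeds, package version and input checksums;
identical inputs and seeds give identical manifests and outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as co
from . import enrichment as en
from . import interaction as ia
from . import nonadditive as na
from . import normalize as nm
from . import synthetic as sy

logger = logging.getLogger("ifnsynergy")
if not logger.handlers:
    _h = logging.StreamHandler()  # stderr, per-stage timers and gene counts
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the analysis' stated values.

    padj 0.05 (interaction and DEG significance), |delta| > 1 log2
    (substantial non-additivity), min 2 TPM expression for response genes,
    min 3 TPM cohort expression filter, top 2,000 expressed genes for PCA,
    1,000 gene-set permutations, core genes in >= 3 leading edges.
    """

    padj_threshold: float = 0.05
    min_abs_delta: float = 1.0
    min_tpm_expression: float = 2.0
    min_tpm_filter: float = 3.0
    top_k_genes: int = 2000
    n_permutations: int = 1000
    min_core_occurrence: int = 3
    bh_alpha: float = 0.1
    restrict_to_response_genes: bool = True
    seed: int = 0
    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    untreated_path: str | None = None
    treated_path: str | None = None
    metadata_path: str | None = None
    mitf_gene: str = "MITF"
    pdl1_gene: str = "CD274"
    simulate: bool = True
    sim_factorial: dict = field(default_factory=dict)
    sim_cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "padj_threshold", "min_abs_delta", "min_tpm_expression",
            "min_tpm_filter", "top_k_genes", "n_permutations", "min_core_occurrence",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir, config: PipelineConfig, inputs: dict[str, str]) -> str:
    payload = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {k: _checksum(v) for k, v in inputs.items()},
    }
    payload["hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path


class _Stage:
    """Context manager: per-stage timing and failure attribution."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s: FAILED: %s", self.name, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.name, time.time() - self.t0)


def run_factorial_pipeline(config: PipelineConfig, outdir) -> dict[str, str]:
    """Counts -> fits -> non-additive calls -> enrichment, with manifest."""
    os.makedirs(outdir, exist_ok=True)
    inputs: dict[str, str] = {}

    with _Stage("load"):
        if config.simulate:
            sim_cfg = sy.SimFactorialConfig(seed=config.seed, **config.sim_factorial)
            counts, design, truth = sy.generate_factorial(sim_cfg)
            paths = sy.write_fixture_bundle(counts, design, truth, os.path.join(outdir, "input"))
            inputs.update(paths)
            gene_sets = en.read_gmt(paths["gmt"])
        else:
            for name, p in (("counts", config.counts_path), ("design", config.design_path)):
                if p is None or not os.path.exists(p or ""):
                    raise FileNotFoundError(f"missing {name} file: {p}")
            counts = ia.read_counts_tsv(config.counts_path)
            design = ia.read_design_tsv(config.design_path)
            inputs = {"counts": config.counts_path, "design": config.design_path}
            gene_sets = en.read_gmt(config.gmt_path) if config.gmt_path else None
        logger.info("loaded %d genes x %d samples", *counts.shape)

    with _Stage("fit"):
        s = ia.estimate_size_factors(counts)
        alpha = ia.estimate_dispersion(counts, design, s)
        fits = ia.fit_interaction(counts, design, s, alpha)
        fits_path = os.path.join(outdir, "gene_fits.tsv")
        fits.to_csv(fits_path, sep="\t", index_label="gene")

    with _Stage("classify"):
        # pseudo-TPM from normalised counts for the expression filter
        norm = counts.div(s, axis=1)
        pseudo_tpm = nm.AbundanceMatrix(norm / norm.sum(axis=0) * 1e6, "TPM")
        retained = ia.response_gene_filter(
            fits, pseudo_tpm,
            padj_threshold=config.padj_threshold,
            min_tpm=config.min_tpm_expression,
            min_abs_lfc=config.min_abs_delta,
        )
        logger.info("%d response genes retained", len(retained))
        thr = na.Thresholds(config.padj_threshold, config.min_abs_delta, config.padj_threshold)
        calls, summary = na.classify_all(
            fits, retained if config.restrict_to_response_genes else None, thr
        )
        calls_path = os.path.join(outdir, "nonadditive_calls.tsv")
        calls.to_csv(calls_path, sep="\t", index_label="gene")
        with open(os.path.join(outdir, "category_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("non-additive categories: %s", summary)

    with _Stage("enrich"):
        if gene_sets is not None and len(gene_sets):
            nonadd_genes = calls.index[calls["is_nonadditive"] == True]  # noqa: E712
            enr = en.overlap_enrichment(nonadd_genes, gene_sets, counts.index)
            enr.to_csv(os.path.join(outdir, "overlap_enrichment.tsv"), sep="\t")

    manifest = _write_manifest(outdir, config, inputs)
    return {"fits": fits_path, "calls": calls_path, "manifest": manifest, "outdir": str(outdir)}


def run_cohort_pipeline(config: PipelineConfig, outdir) -> dict[str, str]:
    """Paired cohort matrices -> strata, associations, PCA, enrichment."""
    os.makedirs(outdir, exist_ok=True)
    inputs: dict[str, str] = {}

    with _Stage("load"):
        if config.simulate:
            sim_cfg = sy.SimCohortConfig(seed=config.seed, **config.sim_cohort)
            mitf_gene, pdl1_gene = sim_cfg.MITF_GENE, sim_cfg.PDL1_GENE
            untreated, treated, metadata, latent = sy.generate_cohort(sim_cfg)
            table = co.CohortTable(untreated, treated, metadata)
            input_dir = os.path.join(outdir, "input")
            os.makedirs(input_dir, exist_ok=True)
            for name, m in (("untreated", untreated), ("treated", treated)):
                p = os.path.join(input_dir, f"{name}_tpm.tsv")
                nm.write_abundance_tsv(m, p)
                inputs[name] = p
        else:
            mitf_gene, pdl1_gene = config.mitf_gene, config.pdl1_gene
            for name, p in (
                ("untreated", config.untreated_path),
                ("treated", config.treated_path),
                ("metadata", config.metadata_path),
            ):
                if p is None or not os.path.exists(p):
                    raise FileNotFoundError(f"missing {name} file: {p}")
            untreated = nm.read_abundance_tsv(config.untreated_path, "TPM")
            treated = nm.read_abundance_tsv(config.treated_path, "TPM")
            unpaired = set(untreated.samples) ^ set(treated.samples)
            if unpaired:
                raise ValueError(
                    f"unpaired line(s) between arms: {', '.join(sorted(map(str, unpaired)))}"
                )
            metadata = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
            table = co.CohortTable(
                untreated,
                nm.AbundanceMatrix(treated.values[list(untreated.samples)], "TPM"),
                metadata,
            )
            inputs = {
                "untreated": config.untreated_path,
                "treated": config.treated_path,
                "metadata": config.metadata_path,
            }

    with _Stage("normalize"):
        table = co.filter_wildtype(table)
        logger.info("%d wild-type lines retained", len(table.lines))
        # the min-TPM filter looks across both arms so paired genes stay paired
        combined = pd.concat([table.untreated.values, table.treated.values], axis=1)
        keep = combined.max(axis=1) >= config.min_tpm_filter
        logger.info("%d/%d genes pass the TPM filter", int(keep.sum()), len(keep))
        un = nm.log2_tpm1(nm.AbundanceMatrix(table.untreated.values.loc[keep], "TPM"))
        tr = nm.log2_tpm1(nm.AbundanceMatrix(table.treated.values.loc[keep], "TPM"))

    with _Stage("stratify"):
        isg = [g for g in tr.genes if str(g).startswith("ISG")]
        score_set = isg if isg else list(tr.genes)
        scores = co.ifng_response_score(tr, score_set)
        mitf = tr.values.loc[mitf_gene]
        pdl1 = tr.values.loc[pdl1_gene]
        halves = co.rank_and_split(mitf, "halves")
        quartiles = co.rank_and_split(mitf, "quartiles")
        low_lines = quartiles[quartiles == "low"].index
        pdl1_split = co.split_high_low(pdl1.loc[low_lines], "largest_gap")
        strata = pd.DataFrame(
            {
                "ifng_response_score": scores,
                "mitf": mitf,
                "pdl1": pdl1,
                "mitf_half": halves,
                "mitf_quartile": quartiles,
            }
        )
        strata["pdl1_group"] = pdl1_split.reindex(strata.index)
        strata_path = os.path.join(outdir, "strata.tsv")
        strata.to_csv(strata_path, sep="\t", index_label="line")

    with _Stage("associate"):
        assoc = {
            "pdl1_vs_ifng_score": vars(co.associate(scores, pdl1, "spearman")),
            "pdl1_vs_mitf": vars(co.associate(mitf, pdl1, "spearman")),
            "pdl1_vs_mitf_linreg": vars(co.associate(mitf, pdl1, "linreg")),
            "pdl1_by_mitf_half": vars(
                co.compare_groups(pdl1, halves, "two_group")
            ),
        }
        for v in assoc.values():
            v.pop("extras", None)
        with open(os.path.join(outdir, "associations.json"), "w") as fh:
            json.dump(assoc, fh, indent=2, sort_keys=True)

    with _Stage("pca"):
        z = nm.zscore_genes(tr)
        k = min(config.top_k_genes, z.values.shape[0])
        pca_scores, _, explained = co.pca_embed(z, k)
        pca_scores.to_csv(os.path.join(outdir, "pca_scores.tsv"), sep="\t", index_label="line")

    with _Stage("enrich"):
        extreme = quartiles.isin(["high", "low"])
        ranked = en.rank_genes(
            nm.zscore_genes(
                nm.AbundanceMatrix(tr.values.loc[:, extreme[extreme].index], "log2TPM1")
            ),
            quartiles[extreme].map({"low": "MITF_low", "high": "MITF_high"}),
        )
        sets = en.GeneSetCollection({"ISG_induced": score_set}) if isg else None
        if config.gmt_path:
            sets = en.read_gmt(config.gmt_path)
        results_path = None
        if sets is not None:
            results = en.permutation_test(
                ranked, sets, n_perm=config.n_permutations, seed=config.seed
            )
            core = en.core_genes(
                list(results["leading_edge"]), min_occurrence=min(
                    config.min_core_occurrence, max(len(results), 1)
                )
            )
            out = results.copy()
            out["leading_edge"] = out["leading_edge"].map(",".join)
            results_path = os.path.join(outdir, "enrichment.tsv")
            out.to_csv(results_path, sep="\t")
            core.to_csv(os.path.join(outdir, "core_genes.tsv"), sep="\t", index_label="gene")

    manifest = _write_manifest(outdir, config, inputs)
    artifacts = {"strata": strata_path, "manifest": manifest, "outdir": str(outdir)}
    if results_path:
        artifacts["enrichment"] = results_path
    return artifacts
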