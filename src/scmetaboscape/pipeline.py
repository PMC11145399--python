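"""End-to-end pipeline: simulate -> QC -> normalize -> (impute) ->
pathway activity -> per-cell GSVA -> metabolic clustering -> markers ->
signature -> survival.

One YAML config drives the whole run; every random stage has an explicit
seed derived from the config seed, so a re-run from the same config
produces byte-identical primary outputs. A run manifest records per-stage
parameters and content hashes of the outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time as time_mod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, enrichment, markers, pathway_activity, preprocess, simulate, survival
from .io import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Defaults follow the analysis's operating point: QC 500 genes / 1,000
    UMIs / 20% mitochondrial, dropout threshold 0.5, deconvolution size
    factors, k = 2 metabolic clusters, 10 PCs and resolution 0.1 for
    re-clustering, min_pct 0.25 and log2FC 0.25 for markers.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulation
    n_genes: int = 1200
    n_cells: int = 800
    n_cell_types: int = 4
    n_samples: int = 4
    n_pathways: int = 15
    genes_per_pathway: int = 20
    pathway_overlap_fraction: float = 0.2
    planted_split_fraction: float = 0.5
    planted_split_boost: float = 3.0
    # QC
    min_genes: int = 100
    min_umis: int = 200
    max_mito: float = 0.20
    # preprocessing
    impute: bool = False
    drop_thre: float = 0.5
    normalization: str = "deconvolution"
    # pathway activity
    n_perm: int = 200
    # clustering
    k: int = 2
    n_pcs: int = 10
    resolution: float = 0.1
    # markers / signature
    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    signature_n: int = 8
    # survival
    bulk_n_samples: int = 400
    bulk_hazard_ratio: float = 2.0
    bulk_censor_rate: float = 0.3
    minprop: float = 0.1

    def __post_init__(self) -> None:
        errors = []
        if not 0.0 < self.drop_thre <= 1.0:
            errors.append(f"drop_thre = {self.drop_thre} outside (0, 1]")
        if not 0.0 <= self.max_mito <= 1.0:
            errors.append(f"max_mito = {self.max_mito} outside [0, 1]")
        if self.normalization not in ("deconvolution", "RLE", "TMM", "upperquartile"):
            errors.append(f"unknown normalization {self.normalization!r}")
        if self.n_perm < 100:
            errors.append(f"n_perm = {self.n_perm} < 100")
        if self.k < 2:
            errors.append(f"k = {self.k} < 2")
        if self.resolution <= 0:
            errors.append(f"resolution = {self.resolution} must be > 0")
        if not 0.0 < self.minprop < 0.5:
            errors.append(f"minprop = {self.minprop} outside (0, 0.5)")
        if self.signature_n < 1:
            errors.append(f"signature_n = {self.signature_n} < 1")
        if not isinstance(self.seed, int):
            errors.append("seed must be an integer")
        if errors:
            raise ConfigError("; ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        errors = validate_config_dict(raw)
        if errors:
            raise ConfigError("; ".join(errors))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config_dict(raw: dict) -> list[str]:
    """Check a raw config mapping: unknown keys (with a suggestion), types
    and ranges. Returns the aggregated list of error strings (empty = ok)."""
    errors = []
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown config key {key!r}{suffix}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    coherent = {k: v for k, v in raw.items() if k in known}
    if not errors:
        try:
            PipelineConfig(**coherent)
        except ConfigError as err:
            errors.extend(str(err).split("; "))
        except TypeError as err:
            errors.append(str(err))
    return errors


def validate_config(path: str | Path) -> list[str]:
    """Validate a YAML config file; returns a list of errors (empty = ok)."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as err:
        return [f"config not parseable: {err}"]
    if not isinstance(raw, dict):
        return ["config must be a key-value mapping"]
    return validate_config_dict(raw)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)

    def record(self, name: str, parameters: dict, outputs: dict[str, str],
               status: str, seconds: float, warnings: list | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "parameters": parameters,
                "outputs": outputs,
                "status": status,
                "seconds": round(seconds, 3),
                "warnings": warnings or [],
            }
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2,
                      default=str)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> str:
    frame.to_csv(path, sep="\t", float_format="%.10g")
    return _hash_file(path)


def run(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline on a simulated dataset.

    Every stage writes its primary output as TSV under ``config.out_dir``
    and records a content hash in the returned manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time_mod.perf_counter()
                self_inner.outputs = {}
                self_inner.params = {}
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                status = "ok" if exc is None else f"failed: {exc}"
                manifest.record(
                    name, self_inner.params, self_inner.outputs, status,
                    time_mod.perf_counter() - self_inner.t0,
                )
                if exc is not None:
                    manifest.save(out / "manifest.json")
                return False

        return _Ctx()

    sim_cfg = simulate.SimulationConfig(
        n_genes=config.n_genes,
        n_cells=config.n_cells,
        n_cell_types=config.n_cell_types,
        n_samples=config.n_samples,
        n_pathways=config.n_pathways,
        genes_per_pathway=config.genes_per_pathway,
        pathway_overlap_fraction=config.pathway_overlap_fraction,
        planted_split_fraction=config.planted_split_fraction,
        planted_split_boost=config.planted_split_boost,
        seed=config.seed,
    )

    with stage("simulate") as st:
        counts, truth = simulate.simulate_dataset(sim_cfg)
        st.params = {"seed": config.seed, "n_cells": config.n_cells}
        simulate.write_dataset(counts, truth, out / "simulated")
        st.outputs["ground_truth.tsv"] = _hash_file(out / "simulated" / "ground_truth.tsv")
    pathways = truth.pathways
    assert pathways is not None

    with stage("qc") as st:
        thresholds = preprocess.QCThresholds(
            min_genes=config.min_genes, min_umis=config.min_umis,
            max_mito_fraction=config.max_mito,
        )
        counts, report = preprocess.qc_filter_cells(counts, thresholds)
        st.params = dataclasses.asdict(thresholds)
        st.outputs["qc_report.tsv"] = _write_tsv(report.to_frame(), out / "qc_report.tsv")

    with stage("normalize") as st:
        factors = preprocess.size_factors(counts, method=config.normalization)
        norm = preprocess.normalize(counts, factors)
        st.params = {"method": config.normalization}
        st.outputs["size_factors.tsv"] = _write_tsv(
            factors.factors.to_frame("size_factor"), out / "size_factors.tsv"
        )

    if config.impute:
        with stage("impute") as st:
            model = preprocess.fit_dropout_model(norm, groups="sample")
            norm = preprocess.impute_dropouts(norm, model, drop_thre=config.drop_thre)
            st.params = {"drop_thre": config.drop_thre}
            dropped = pd.DataFrame(
                {"mean_dropout_probability": model.dropout_probability.mean(axis=1)},
                index=norm.gene_ids,
            )
            st.outputs["dropout_rates.tsv"] = _write_tsv(dropped, out / "dropout_rates.tsv")

    with stage("score_pathways") as st:
        observed = pathway_activity.score_pipeline(norm, pathways)
        observed.condition = "tumor"
        activity = pathway_activity.permutation_test(
            norm, pathways, observed, n_perm=config.n_perm, seed=config.seed + 1
        )
        st.params = {"n_perm": config.n_perm, "seed": config.seed + 1}
        st.outputs["pathway_activity.tsv"] = _write_tsv(
            activity.to_long(pathways.category), out / "pathway_activity.tsv"
        )

    with stage("gsva") as st:
        malignant = norm.subset_columns(
            (norm.annotation("cell_type") == sim_cfg.malignant_cell_type).values
        )
        mal_log = malignant.with_values(np.log1p(malignant.values), units="lognorm")
        scores = enrichment.gsva_scores(mal_log, pathways)
        st.params = {"kernel": scores.kernel, "tau": scores.tau}
        st.outputs["gsva_scores.tsv"] = _write_tsv(scores.scores, out / "gsva_scores.tsv")

    with stage("cluster_metabolic") as st:
        split = clustering.hierarchical_split(scores, k=config.k)
        named = clustering.label_high_low(split, scores)
        st.params = {"k": config.k}
        st.outputs["metabolic_clusters.tsv"] = _write_tsv(
            named.labels.to_frame(), out / "metabolic_clusters.tsv"
        )

    with stage("markers") as st:
        de = markers.find_markers(
            mal_log, named.labels,
            min_pct=config.min_pct, logfc_threshold=config.logfc_threshold,
        )
        st.params = {"min_pct": config.min_pct, "logfc_threshold": config.logfc_threshold}
        st.outputs["markers.tsv"] = _write_tsv(
            de.table.set_index("gene"), out / "markers.tsv"
        )

    with stage("signature") as st:
        sig = markers.top_n_signature(de, "high", n=config.signature_n)
        st.params = dict(sig.provenance)
        sig_frame = pd.DataFrame({"gene": sig.genes}).set_index("gene")
        st.outputs["signature.tsv"] = _write_tsv(sig_frame, out / "signature.tsv")

    with stage("survival") as st:
        bundle = simulate.simulate_bulk_survival(
            n_samples=config.bulk_n_samples,
            signature=sig.genes if len(sig.genes) >= 3 else list(norm.gene_ids[:8]),
            hazard_ratio=config.bulk_hazard_ratio,
            censor_rate=config.bulk_censor_rate,
            seed=config.seed + 2,
        )
        bulk_scores = survival.score_bulk(
            bundle["expression"].with_values(
                np.log1p(bundle["expression"].values), units="lognorm"
            ),
            sig if len(sig.genes) >= 3 else list(norm.gene_ids[:8]),
        )
        cohort_frame = bundle["cohort"].copy()
        cohort_frame["score"] = bulk_scores
        cohort = survival.SurvivalCohort(cohort_frame)
        cut = survival.optimal_cutpoint(cohort, minprop=config.minprop)
        km = survival.km_logrank(cohort, cut.cutpoint)
        cox = survival.cox_multivariate(cohort, covariates=[])
        st.params = {"minprop": config.minprop, "seed": config.seed + 2}
        summary = pd.DataFrame(
            {
                "quantity": ["cutpoint", "logrank_chi2", "logrank_p",
                             "cox_score_hr", "n_low", "n_high"],
                "value": [cut.cutpoint, km["chi2"], km["p"],
                          cox.loc["score_term", "hazard_ratio"],
                          km["n_low"], km["n_high"]],
            }
        ).set_index("quantity")
        st.outputs["survival_summary.tsv"] = _write_tsv(summary, out / "survival_summary.tsv")
        st.outputs["cox.tsv"] = _write_tsv(cox, out / "cox.tsv")

    manifest.save(out / "manifest.json")
    return manifest
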