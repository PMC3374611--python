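"""End-to-end driver: qc -> sam -> cluster -> compose -> mancova -> screen.

Chains the stage modules on either a synthetic cohort or three on-disk
tables, writes every stage's outputs as tab-separated text plus a JSON run
manifest (parameters, seed, table shapes per stage), and is deterministic
under a fixed global seed: per-stage random streams are derived from the
global seed by stage-name hashing, so a stage re-run in isolation
reproduces its in-pipeline result.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_table import summarize_cohort
from .correlation_screen import stratified_correlations
from .expression_qc import average_technical_duplicates, filter_absent_probes
from .gene_clustering import cluster_genes
from .io import (
    align_samples,
    read_counts,
    read_expression,
    read_metadata,
    read_taxonomy,
    write_table,
)
from .perm_mancova import DesignVariable, stepwise_select
from .sam_select import SamConfig, pairwise_union, sam_analyze
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort
from .taxa_composition import bin_to_categories, clr_transform

logger = logging.getLogger("ileum_integrate")

STAGES = ("qc", "sam", "cluster", "compose", "mancova", "screen")

#: metadata columns offered as MANCOVA candidates alongside the centroids
CANDIDATE_COVARIATES = (
    ("phenotype", "categorical"),
    ("age", "continuous"),
    ("race", "categorical"),
    ("smoker", "categorical"),
    ("bmi", "continuous"),
    ("gender", "categorical"),
    ("cdiff", "categorical"),
    ("asa5", "categorical"),
    ("steroids", "categorical"),
    ("immunomod", "categorical"),
    ("anti_tnf", "categorical"),
    ("nod2", "categorical"),
    ("atg16l1", "categorical"),
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stage-name CRC mixing)."""
    return int((global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31))


@dataclass
class PipelineConfig:
    """Paths, per-stage parameters and the global seed of one run."""

    output_dir: Path
    expression_path: Optional[Path] = None
    flags_path: Optional[Path] = None
    counts_path: Optional[Path] = None
    taxonomy_path: Optional[Path] = None
    metadata_path: Optional[Path] = None
    synth: Optional[dict] = None  # CohortConfig overrides; used when paths absent
    seed: int = 0
    flag_threshold: int = -50
    duplicate_map: dict = field(default_factory=dict)
    sam: dict = field(default_factory=dict)  # SamConfig overrides
    cluster_k: int = 8
    centroid_method: str = "median"
    linkage_input: str = "sqrt2d"
    pseudocount_mode: str = "add_half_read"
    alpha_enter: float = 0.05
    n_perm: int = 999
    scheme: str = "freedman_lane"
    forced_first: Optional[list] = None
    screen_genes: Optional[list] = None
    screen_genera: Optional[list] = None
    screen_alpha: float = 0.05
    screen_method: str = "pearson"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["output_dir"] = Path(raw.get("output_dir", "results"))
        for key in ("expression_path", "flags_path", "counts_path", "taxonomy_path", "metadata_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def _mark_partial(paths: list[Path]) -> None:
    for p in paths:
        if p.exists():
            p.rename(p.with_suffix(p.suffix + ".partial"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the result bundle.

    The bundle holds the in-memory stage products plus the manifest.  Any
    stage failure aborts with :class:`PipelineError` naming the stage;
    files already written by the failing stage are kept with a
    ``.partial`` suffix.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}
    stage_files: list[Path] = []

    def record(stage: str, **info):
        manifest["stages"][stage] = info

    def run_stage(stage, fn):
        stage_files.clear()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            _mark_partial(stage_files)
            raise PipelineError(stage, exc) from exc

    # ---- inputs
    def _inputs():
        if config.expression_path is not None:
            expression = read_expression(config.expression_path, config.flags_path)
            counts = read_counts(config.counts_path)
            taxonomy = read_taxonomy(config.taxonomy_path)
            metadata = read_metadata(config.metadata_path)
        else:
            overrides = dict(config.synth or {})
            overrides.setdefault("seed", stage_seed(config.seed, "synth"))
            cohort = generate_cohort(CohortConfig(**overrides))
            stage_files.extend(write_cohort(cohort, out / "synth").values())
            expression, counts = cohort.expression, cohort.taxa_counts
            taxonomy, metadata = cohort.taxonomy, cohort.metadata
            bundle["cohort"] = cohort
        expression, counts, metadata = align_samples(expression, counts, metadata)
        bundle.update(
            expression=expression, counts=counts, taxonomy=taxonomy, metadata=metadata
        )
        record(
            "inputs",
            n_samples=len(expression.sample_ids),
            n_probes=len(expression.probe_ids),
            n_genera=len(counts),
        )

    run_stage("inputs", _inputs)

    # ---- qc
    def _qc():
        m = bundle["expression"]
        if m.flags is not None:
            m = filter_absent_probes(m, config.flag_threshold)
        if config.duplicate_map:
            m = average_technical_duplicates(m, config.duplicate_map)
        bundle["expression_qc"] = m
        stage_files.append(write_table(m.values, out / "expression_qc.tsv", "probe_id"))
        record(
            "qc",
            flag_threshold=config.flag_threshold,
            n_probes=len(m.probe_ids),
            n_samples=len(m.sample_ids),
        )

    run_stage("qc", _qc)

    # ---- sam
    def _sam():
        m = bundle["expression_qc"]
        phen = bundle["metadata"].loc[m.sample_ids, "phenotype"]
        comparisons = [("CD", "Control"), ("UC", "Control"), ("CD", "UC")]
        sam_cfg = dict(config.sam)
        sam_cfg.setdefault("seed", stage_seed(config.seed, "sam"))
        selected = {}
        tables = []
        for a, b in comparisons:
            name = f"{a}vs{b}"
            cols = phen.index[phen.isin([a, b])]
            res = sam_analyze(
                m.values[cols], phen.loc[cols], SamConfig(**sam_cfg), classes=(b, a)
            )
            t = res.table.copy()
            t.insert(0, "comparison", name)
            tables.append(t)
            selected[name] = set(res.called)
        union, venn = pairwise_union(selected)
        bundle["sam_selected"] = sorted(union)
        bundle["sam_tables"] = pd.concat(tables)
        stage_files.append(
            write_table(bundle["sam_tables"], out / "sam_probes.tsv", "probe_id")
        )
        venn_df = pd.DataFrame(
            [("+".join(k), v) for k, v in venn.items()], columns=["region", "count"]
        )
        stage_files.append(write_table(venn_df.set_index("region"), out / "sam_venn.tsv"))
        record(
            "sam",
            **{k: v for k, v in sam_cfg.items()},
            n_selected=len(union),
            venn={"+".join(k): v for k, v in venn.items()},
        )

    run_stage("sam", _sam)

    # ---- cluster
    def _cluster():
        m = bundle["expression_qc"]
        probes = bundle["sam_selected"]
        sam_bypassed = False
        # differential-expression pre-selection is a dimension-reduction aid;
        # with (near-)no calls, cluster the full QC'd probe set instead
        if len(probes) < max(2 * config.cluster_k, 20):
            logger.warning(
                "only %d probes selected by SAM; clustering all %d QC'd probes",
                len(probes),
                len(m.probe_ids),
            )
            probes = list(m.values.index)
            sam_bypassed = True
        sol = cluster_genes(
            m.values.loc[probes],
            k=config.cluster_k,
            centroid_method=config.centroid_method,
            linkage_input=config.linkage_input,
        )
        bundle["clusters"] = sol
        stage_files.append(
            write_table(sol.assignment.to_frame(), out / "cluster_assignment.tsv", "probe_id")
        )
        stage_files.append(write_table(sol.centroids, out / "cluster_centroids.tsv", "cluster"))
        stage_files.append(
            write_table(sol.r2_curve.to_frame(), out / "cluster_r2_curve.tsv", "k")
        )
        record(
            "cluster",
            k=config.cluster_k,
            centroid_method=config.centroid_method,
            linkage_input=config.linkage_input,
            n_probes=len(probes),
            sam_bypassed=sam_bypassed,
        )

    run_stage("cluster", _cluster)

    # ---- compose
    def _compose():
        comp = bin_to_categories(bundle["counts"], bundle["taxonomy"].to_dict())
        clr = clr_transform(comp, pseudocount_mode=config.pseudocount_mode)
        bundle["composition"] = comp
        bundle["clr"] = clr
        stage_files.append(
            write_table(comp.frequencies, out / "category_frequencies.tsv", "sample_id")
        )
        stage_files.append(write_table(clr, out / "clr.tsv", "sample_id"))
        record("compose", pseudocount_mode=config.pseudocount_mode, n_samples=len(clr))

    run_stage("compose", _compose)

    # ---- mancova
    def _mancova():
        clr = bundle["clr"]
        metadata = bundle["metadata"].loc[clr.index]
        centroids = bundle["clusters"].centroids
        candidates = [
            DesignVariable(
                f"cluster_{lab}", "continuous", centroids.loc[lab, clr.index]
            )
            for lab in centroids.index
        ]
        for col, kind in CANDIDATE_COVARIATES:
            if col not in metadata.columns:
                continue
            s = metadata[col]
            if s.isna().any():
                keep = s.notna()
                logger.warning(
                    "dropping %d samples with missing %s", int((~keep).sum()), col
                )
                continue
            if kind == "categorical" and s.nunique() < 2:
                continue
            candidates.append(
                DesignVariable(col, kind, s.astype(float) if kind == "continuous" else s)
            )
        trace, final = stepwise_select(
            clr,
            candidates,
            alpha_enter=config.alpha_enter,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "mancova"),
            scheme=config.scheme,
            forced_first=config.forced_first,
        )
        bundle["stepwise"] = trace
        bundle["mancova"] = final
        stage_files.append(write_table(trace.entries, out / "stepwise_trace.tsv"))
        if final is not None:
            stage_files.append(write_table(final.table, out / "mancova_table.tsv", "term"))
        record(
            "mancova",
            alpha_enter=config.alpha_enter,
            n_perm=config.n_perm,
            scheme=config.scheme,
            selected=list(trace.entries["term"]),
        )

    run_stage("mancova", _mancova)

    # ---- screen
    def _screen():
        m = bundle["expression_qc"]
        clr_index = bundle["clr"].index
        metadata = bundle["metadata"].loc[clr_index]
        genes = config.screen_genes
        if genes is None:
            # default panel: probes of the clusters whose centroid entered
            sol = bundle["clusters"]
            selected_clusters = [
                int(t.split("_", 1)[1])
                for t in bundle["stepwise"].entries["term"]
                if t.startswith("cluster_")
            ]
            if selected_clusters:
                genes = [
                    p
                    for lab in selected_clusters
                    for p in sol.assignment.index[sol.assignment == lab][:10]
                ]
            else:
                best_d = bundle["sam_tables"]["d"].abs().groupby(level=0).max()
                genes = list(best_d.sort_values(ascending=False).index[:10])
        genes = list(dict.fromkeys(genes))
        genera = config.screen_genera or list(bundle["counts"].index)
        freqs = bundle["counts"].div(bundle["counts"].sum(axis=0), axis=1)
        grid = stratified_correlations(
            m.values.loc[[g for g in genes if g in m.values.index]],
            freqs.loc[[g for g in genera if g in freqs.index]],
            metadata["phenotype"],
            method=config.screen_method,
            alpha=config.screen_alpha,
        )
        bundle["screen"] = grid
        stage_files.append(write_table(grid.table, out / "correlation_grid.tsv"))
        stage_files.append(write_table(grid.flag_matrix(), out / "correlation_flags.tsv"))
        record(
            "screen",
            alpha=config.screen_alpha,
            method=config.screen_method,
            n_genes=len(genes),
            n_genera=len(genera),
        )

    run_stage("screen", _screen)

    # cohort summary (descriptive; not a numbered stage)
    try:
        summary = summarize_cohort(bundle["metadata"])
        bundle["cohort_summary"] = summary
        write_table(summary.table, out / "cohort_summary.tsv", "variable")
    except ValueError as exc:
        logger.warning("cohort summary skipped: %s", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return bundle
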