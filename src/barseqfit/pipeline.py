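"""End-to-end orchestration: counting, fitness, profiles, clustering, and
truth-based evaluation of simulated runs.

``run_pipeline`` executes the four analysis stages, writing every
intermediate as TSV plus a machine-readable manifest (all parameters, seed,
input checksums) so that a rerun with the same configuration reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__, io as bio
from .barcodes import FlankSpec, assemble_count_table, count_fastq_file, top_percentile_share
from .cluster import (
    ArchetypeThresholds,
    ClusterAssignment,
    cofitness_matrix,
    hierarchical_cluster,
    label_archetypes,
    profile_distance,
)
from .errors import InputError, PipelineError
from .fitness import FitnessParams, GeneFitness, center_fitness, gene_fitness, strain_fitness
from .profiles import ProfileSet, aggregate_replicates, condition_normalize, rank_and_select, sd_filter

logger = logging.getLogger(__name__)

# Expected archetype for each planted truth class; neutral and pure growth
# defects have flat normalized profiles, hence no archetype.
TRUTH_TO_ARCHETYPE = {
    "nonadhesive_strong": "biosynthesis",
    "nonadhesive_mild": "modification",
    "hyperadhesive": "hyperadhesive",
    "recovery": "recovery",
    "growth_defect": "unclassified",
    "neutral": "unclassified",
}


@dataclass
class RunConfig:
    pool_path: str
    sheet_path: str
    out_dir: str
    counts_path: str | None = None  # counts mode
    fastq_dir: str | None = None  # fastq mode: <sample_id>.fastq per sample
    flanks: FlankSpec = field(default_factory=FlankSpec)
    fitness_params: FitnessParams = field(default_factory=FitnessParams)
    top_k: int = 250
    metric: str = "euclidean"
    linkage: str = "ward"
    n_clusters: int = 6
    thresholds: ArchetypeThresholds = field(default_factory=ArchetypeThresholds)
    seed: int = 0

    @property
    def mode(self) -> str:
        return "counts" if self.counts_path is not None else "fastq"

    def validate(self) -> None:
        if (self.counts_path is None) == (self.fastq_dir is None):
            raise InputError("exactly one of counts_path / fastq_dir required")
        for p in (self.pool_path, self.sheet_path, self.counts_path, self.fastq_dir):
            if p is not None and not Path(p).exists():
                raise InputError(f"input path does not exist: {p}")
        if self.top_k < 1:
            raise InputError("top_k must be >= 1")


@dataclass
class PipelineResult:
    counts: pd.DataFrame
    sheet: pd.DataFrame
    pool: pd.DataFrame
    gene_fitness: GeneFitness
    profiles: ProfileSet
    normalized: pd.DataFrame  # all genes with complete grids
    selected: pd.DataFrame  # top-k table (locus index, score, rank)
    clusters: ClusterAssignment
    archetypes: pd.Series
    qc: pd.DataFrame
    out_dir: Path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute count -> fitness -> profiles -> clustering and write artifacts."""
    config.validate()
    out = bio.ensure_dir(config.out_dir)
    manifest: dict = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "parameters": _jsonable(config),
        "inputs": {},
        "stages_complete": [],
    }
    stage = "setup"
    try:
        pool = bio.read_pool(config.pool_path)
        sheet = bio.read_sheet(config.sheet_path)
        manifest["inputs"][str(config.pool_path)] = _sha256(config.pool_path)
        manifest["inputs"][str(config.sheet_path)] = _sha256(config.sheet_path)

        stage = "count"
        if config.mode == "counts":
            counts = bio.read_counts(config.counts_path)
            manifest["inputs"][str(config.counts_path)] = _sha256(config.counts_path)
            missing = set(sheet["sample_id"]) - set(counts.columns)
            if missing:
                raise InputError(f"sheet samples missing from counts: {sorted(missing)}")
            counts = counts.reindex(pool["barcode"], fill_value=0)
            counts.index.name = "barcode"
            unmapped = pd.DataFrame(
                {"sample_id": list(counts.columns), "unmapped_reads": 0, "unmapped_fraction": 0.0}
            )
        else:
            per_sample = {}
            for sample_id in sheet["sample_id"]:
                path = Path(config.fastq_dir) / f"{sample_id}.fastq"
                if not path.exists():
                    raise InputError(f"missing FASTQ for sample {sample_id}: {path}")
                manifest["inputs"][str(path)] = _sha256(path)
                mapping, stats = count_fastq_file(path, config.flanks)
                logger.info(
                    "count %s: %d reads, %d with barcode, %d distinct",
                    sample_id, stats.total_reads, stats.reads_with_barcode,
                    stats.distinct_barcodes,
                )
                per_sample[sample_id] = mapping
            counts, unmapped = assemble_count_table(per_sample, pool, sheet)
            high = unmapped[unmapped["unmapped_fraction"] > 0.10]
            for _, row in high.iterrows():
                logger.warning(
                    "sample %s: unmapped-read fraction %.3f",
                    row["sample_id"], row["unmapped_fraction"],
                )
        qc = unmapped.set_index("sample_id")
        qc["top1pct_share"] = [
            top_percentile_share(counts[s], 1.0) for s in qc.index
        ]
        bio.write_counts(counts, out / "counts.tsv")
        qc.to_csv(out / "qc.tsv", sep="\t")
        manifest["stages_complete"].append("count")

        stage = "fitness"
        strains = strain_fitness(counts, sheet, config.fitness_params)
        genes = gene_fitness(strains, counts, pool, config.fitness_params)
        genes = center_fitness(genes, config.fitness_params.center)
        _write_strain_fitness(strains, out / "strain_fitness.tsv")
        _write_gene_fitness(genes, out / "gene_fitness.tsv")
        manifest["stages_complete"].append("fitness")

        stage = "profiles"
        profiles = aggregate_replicates(genes.fitness, sheet)
        filt = sd_filter(profiles)
        normalized = condition_normalize(profiles)
        eligible = normalized.loc[normalized.index.intersection(filt.kept)]
        selected = rank_and_select(eligible, config.top_k)
        _write_profiles(profiles, out / "profiles.tsv")
        _write_normalized(normalized, filt, selected, out / "normalized.tsv")
        manifest["stages_complete"].append("profiles")

        stage = "clustering"
        sel_profiles = normalized.loc[selected.index]
        distances, _flagged = profile_distance(sel_profiles, config.metric)
        clusters = hierarchical_cluster(
            distances, config.linkage, min(config.n_clusters, len(distances))
        )
        archetypes = label_archetypes(sel_profiles, config.thresholds)
        cof, _cof_flagged = cofitness_matrix(sel_profiles)
        _write_clusters(clusters, archetypes, selected, out / "clusters.tsv")
        cof.to_csv(out / "cofitness.tsv", sep="\t")
        pd.DataFrame(
            clusters.tree[:, :3], columns=["left", "right", "height"]
        ).to_csv(out / "merge_tree.tsv", sep="\t", index=False)
        manifest["stages_complete"].append("clustering")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    return PipelineResult(
        counts=counts,
        sheet=sheet,
        pool=pool,
        gene_fitness=genes,
        profiles=profiles,
        normalized=normalized,
        selected=selected,
        clusters=clusters,
        archetypes=archetypes,
        qc=qc,
        out_dir=out,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_strain_fitness(strains, path) -> None:
    long = strains.fitness.stack().rename("fitness").reset_index()
    long.columns = ["barcode", "sample", "fitness"]
    long["usable"] = strains.usable.reindex(long["barcode"]).to_numpy()
    long.to_csv(path, sep="\t", index=False)


def _write_gene_fitness(genes: GeneFitness, path) -> None:
    long = genes.fitness.stack().rename("fitness").reset_index()
    long.columns = ["locus", "sample", "fitness"]
    long["n_strains_used"] = genes.n_strains_used.reindex(long["locus"]).to_numpy()
    long.to_csv(path, sep="\t", index=False)


def _write_profiles(profiles: ProfileSet, path) -> None:
    mean = profiles.mean.stack(["condition", "passage"], future_stack=True).rename("mean")
    sd = profiles.sd.stack(["condition", "passage"], future_stack=True).rename("sd")
    long = pd.concat([mean, sd], axis=1).reset_index()
    long["n"] = [
        profiles.n_replicates[(c, p)] for c, p in zip(long["condition"], long["passage"])
    ]
    long.to_csv(path, sep="\t", index=False)


def _write_normalized(normalized, filt, selected, path) -> None:
    out = normalized.copy()
    out.columns = [f"g{p}" for p in normalized.columns]
    out["score"] = normalized.abs().max(axis=1)
    out["kept"] = [locus in set(filt.kept) for locus in out.index]
    rank = selected["rank"]
    out["rank"] = rank.reindex(out.index)
    out.to_csv(path, sep="\t", index=True)


def _write_clusters(clusters, archetypes, selected, path) -> None:
    table = pd.DataFrame(
        {
            "cluster": clusters.labels,
            "archetype": archetypes.reindex(clusters.labels.index),
            "score": selected["score"].reindex(clusters.labels.index),
        }
    )
    table.index.name = "locus"
    table.to_csv(path, sep="\t", index=True)


@dataclass
class EvaluationReport:
    recall_at_k: dict[str, float]
    ari: float
    neutral_bias: float
    confusion: pd.DataFrame  # archetype x truth class, selected genes
    archetype_agreement: float  # selected planted non-neutral genes
    n_selected: int


def evaluate_against_truth(result: PipelineResult, truth: pd.DataFrame) -> EvaluationReport:
    """Score a simulated run against its planted truth labels.

    Computes recall@top_k per planted class, the adjusted Rand index between
    flat clusters and truth classes on selected non-neutral genes, the mean
    absolute normalized fitness of planted neutral genes, the archetype/truth
    confusion table, and archetype agreement (via the expected archetype of
    each truth class) over selected planted non-neutral genes.
    """
    if result.selected.empty:
        raise InputError("empty selection: nothing to evaluate")
    truth_by_locus = truth.set_index("locus")["class"]
    selected = result.selected.index
    recall = {}
    for cls in sorted(truth_by_locus.unique()):
        members = truth_by_locus.index[truth_by_locus == cls]
        evaluable = members.intersection(result.normalized.index)
        if len(evaluable) == 0:
            recall[cls] = float("nan")
        else:
            recall[cls] = len(selected.intersection(evaluable)) / len(evaluable)

    sel_truth = truth_by_locus.reindex(selected)
    non_neutral = selected[(sel_truth != "neutral") & sel_truth.notna()]
    cluster_labels = result.clusters.labels.reindex(non_neutral)
    ari = (
        float(adjusted_rand_score(sel_truth.reindex(non_neutral), cluster_labels))
        if len(non_neutral) >= 2
        else float("nan")
    )

    neutral = truth_by_locus.index[truth_by_locus == "neutral"]
    neutral = neutral.intersection(result.normalized.index)
    neutral_bias = float(result.normalized.loc[neutral].abs().to_numpy().mean())

    arch = result.archetypes.reindex(selected)
    confusion = pd.crosstab(arch, sel_truth.reindex(selected), dropna=False)
    confusion.index.name = "archetype"
    confusion.columns.name = "truth_class"

    expected = sel_truth.reindex(non_neutral).map(TRUTH_TO_ARCHETYPE)
    agreement = (
        float((arch.reindex(non_neutral) == expected).mean())
        if len(non_neutral)
        else float("nan")
    )
    return EvaluationReport(
        recall_at_k=recall,
        ari=ari,
        neutral_bias=neutral_bias,
        confusion=confusion,
        archetype_agreement=agreement,
        n_selected=len(selected),
    )
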