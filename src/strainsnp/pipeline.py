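"""End-to-end orchestration: simulate -> filter -> compare -> annotate ->
similarity -> report, with a reproducible run manifest.

Every stage reads its inputs from files and writes its outputs back to
files, so stages can be re-run or inspected in isolation; the manifest
records the configuration hash, seed and per-stage record counts (the
variant funnel), and reruns with an identical configuration and seed are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_all, read_sift_table, records_to_frame
from .comparison import (
    StrainPanel,
    combination_counts,
    partition_counts,
    profile_variants,
    profiles_to_frame,
    read_strain_categories,
    select_most_common,
)
from .filtering import (
    filter_group,
    read_group_calls,
    read_sample_groups,
    union_across_groups,
    write_filtered_vcf,
)
from .io import read_bed_mask, read_fasta
from .reporting import (
    CandidateRecord,
    candidate_report,
    read_gene_phenotypes,
    sharing_funnel,
    summarize_effect_classes,
)
from .similarity import classical_mds, ibs_matrix, upgma
from .simulate import default_scenario, simulate_to_dir
from .transcripts import read_gtf


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    input_dir: str = "inputs"
    output_dir: str = "outputs"
    seed: int = 0
    simulate: bool = True
    groups: tuple[str, ...] = ()  # empty: discovered from sample_groups.tsv
    min_q: float = 100.0
    min_dp: int = 10
    min_hom: int = 3
    most_common_min: int = 6
    sift_cutoff: float = 0.05
    flank: int = 5000
    sift_table: str | None = None
    phenotype_table: str | None = None
    stages: tuple[str, ...] = (
        "filter", "compare", "annotate", "similarity", "report",
    )

    def __post_init__(self) -> None:
        if self.min_hom < 1 or self.min_dp < 1 or self.min_q <= 0:
            raise ValueError("filter thresholds must be positive")
        if self.most_common_min < 1:
            raise ValueError("most_common_min must be >= 1")
        if not 0 < self.sift_cutoff <= 1:
            raise ValueError("sift_cutoff must be in (0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False

        return _Ctx()

    if config.simulate:
        with _stage("simulate"):
            sim = simulate_to_dir(default_scenario(config.seed), indir)
            counts["simulate:planted_variants"] = len(sim.truth.frame)
            counts["simulate:panel_loci"] = sim.panel.n_loci

    groups = list(config.groups)
    if not groups:
        sample_groups = read_sample_groups(indir / "sample_groups.tsv")
        groups = sorted(set(sample_groups.values()))

    filtered = []
    if "filter" in config.stages:
        with _stage("filter"):
            per_group = []
            for group in groups:
                calls = read_group_calls(indir / f"calls_{group}.vcf", group)
                passed = filter_group(
                    calls, group,
                    min_q=config.min_q, min_dp=config.min_dp,
                    min_hom=config.min_hom,
                )
                counts[f"filter:{group}"] = len(passed)
                per_group.append(passed)
            filtered = union_across_groups(per_group)
            counts["filter:union"] = len(filtered)
            genome_for_contigs = read_fasta(indir / "genome.fa")
            contigs = {k: len(v) for k, v in genome_for_contigs.items()}
            write_filtered_vcf(outdir / "filtered.vcf", filtered, contigs)
            outputs["filtered"] = "filtered.vcf"

    variants = [fv.variant for fv in filtered]
    profiles = []
    panel = None
    if "compare" in config.stages:
        with _stage("compare"):
            categories = read_strain_categories(indir / "strain_categories.tsv")
            coverage = read_bed_mask(indir / "coverage.bed")
            panel = StrainPanel.from_vcf(
                indir / "panel.vcf", categories, coverage_sites=coverage
            )
            covered_panel = panel.restrict_to_covered()
            counts["compare:panel_loci"] = panel.n_loci
            counts["compare:covered_loci"] = covered_panel.n_loci
            profiles = profile_variants(variants, covered_panel)
            control, hypertensive, exclusive = partition_counts(profiles)
            counts["compare:control_shared"] = control
            counts["compare:hypertensive_shared"] = hypertensive
            counts["compare:focal_exclusive"] = exclusive
            profiles_to_frame(profiles).to_csv(
                outdir / "sharing_profiles.tsv", sep="\t", index=False
            )
            outputs["profiles"] = "sharing_profiles.tsv"
            combos = combination_counts(profiles, covered_panel)
            combo_frame = pd.DataFrame(
                {
                    "strains": [";".join(sorted(k)) for k in combos],
                    "n_strains": [len(k) for k in combos],
                    "n_variants": list(combos.values()),
                }
            ).sort_values(
                ["n_strains", "strains"], ascending=[False, True]
            )
            combo_frame.to_csv(
                outdir / "combination_counts.tsv", sep="\t", index=False
            )
            outputs["combinations"] = "combination_counts.tsv"
            most_common = select_most_common(
                profiles, min_strains=config.most_common_min
            )
            counts["compare:most_common"] = len(most_common)

    records = []
    if "annotate" in config.stages:
        with _stage("annotate"):
            genome = read_fasta(indir / "genome.fa")
            transcripts = read_gtf(indir / "transcripts.gtf")
            sift = (
                read_sift_table(config.sift_table)
                if config.sift_table
                else None
            )
            records = annotate_all(
                variants, transcripts, genome,
                flank=config.flank, sift_scores=sift,
            )
            counts["annotate:records"] = len(records)
            records_to_frame(records).to_csv(
                outdir / "annotation.tsv", sep="\t", index=False
            )
            summarize_effect_classes(records).to_csv(
                outdir / "effect_classes.tsv", sep="\t", index=False
            )
            outputs["annotation"] = "annotation.tsv"
            outputs["effect_classes"] = "effect_classes.tsv"

    if "similarity" in config.stages:
        with _stage("similarity"):
            if panel is None:
                raise ValueError("similarity needs the compare stage's panel")
            covered_panel = panel.restrict_to_covered()
            ibs = ibs_matrix(covered_panel.genotypes)
            ibs.to_frame().to_csv(outdir / "ibs_matrix.tsv", sep="\t")
            tree = upgma(ibs.distances, ibs.strains)
            (outdir / "dendrogram.nwk").write_text(str(tree))
            embedding = classical_mds(ibs.distances, ibs.strains, k=2)
            embedding.coordinates.to_csv(outdir / "mds_coordinates.tsv", sep="\t")
            outputs["ibs"] = "ibs_matrix.tsv"
            outputs["dendrogram"] = "dendrogram.nwk"
            outputs["mds"] = "mds_coordinates.tsv"
            counts["similarity:strains"] = len(ibs.strains)

    if "report" in config.stages:
        with _stage("report"):
            phenotypes = (
                read_gene_phenotypes(config.phenotype_table)
                if config.phenotype_table
                else {}
            )
            profile_by_key = {p.variant.key: p for p in profiles}
            best_by_variant: dict[tuple, CandidateRecord] = {}
            impact_rank = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
            for rec in records:
                prof = profile_by_key.get(rec.variant.key)
                cand = CandidateRecord(
                    chrom=rec.variant.chrom,
                    pos=rec.variant.pos,
                    alt=rec.variant.alt,
                    gene=rec.gene_symbol or "",
                    n_hypertensive_carriers=(
                        prof.n_hypertensive_carriers if prof else 1
                    ),
                    impact=rec.impact,
                    sift_class=rec.sift_class,
                    phenotype_flags=phenotypes.get(
                        rec.gene_symbol or "", frozenset()
                    ),
                )
                key = rec.variant.key
                old = best_by_variant.get(key)
                if old is None or impact_rank[cand.impact] < impact_rank[old.impact]:
                    best_by_variant[key] = cand
            report = candidate_report(list(best_by_variant.values()))
            report.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            outputs["candidates"] = "candidates.tsv"
            n_high = sum(
                1 for c in best_by_variant.values() if c.impact == "HIGH"
            )
            n_del = sum(
                1
                for c in best_by_variant.values()
                if c.sift_class == "deleterious"
            )
            funnel = sharing_funnel(
                len(variants),
                partition_counts(profiles),
                counts.get("compare:most_common", 0),
                n_high,
                n_del,
            )
            funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
            outputs["funnel"] = "funnel.tsv"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_counts": counts,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
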