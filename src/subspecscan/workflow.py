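"""Run the whole analysis from one declarative config.

Stages run in dependency order — genotype screen, per-gene site
classification and diversity, gene tree with bootstrap, homoplasy census
under each configured guide tree, inter-gene LD — and each stage's outputs
are written under the run directory with SHA-256 checksums recorded in the
report. A stage that fails is marked failed and independent later stages
still run. Stochastic stages (the bootstrap) have no hidden default seed:
omitting the seed is a config error, so a run is reproducible or it does
not start.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import GroupPartition, MultiStrainAlignment
from .ld import concatenate, r2_matrix
from .phylo import (
    ancestral_changes,
    bootstrap_support,
    detect_homoplasies,
    f84_distance_matrix,
    neighbor_joining,
)
from .screen import (
    StrainGenotypeTable,
    count_differences_per_gene,
    rank_candidates,
    read_gene_intervals,
    write_screen_report,
)
from .varsites import SiteCategory, classify_sites, count_categories, diversity

logger = logging.getLogger(__name__)


@dataclass
class GeneConfig:
    gene_id: str
    fasta: str
    frame_offset: int = 0


@dataclass
class RunConfig:
    """Declarative inputs for one pipeline run; any section may be omitted
    and only the stages it feeds are skipped."""

    outdir: str
    genotype_table: str | None = None
    gene_intervals: str | None = None
    screen_strains: tuple[str, str] | None = None
    screen_top_k: int = 10
    exclude_pseudogenes: bool = False
    genes: list[GeneConfig] = field(default_factory=list)
    groups: str | None = None
    guide_trees: dict[str, str] = field(default_factory=dict)
    tree_gene: str | None = None  # gene used for NJ tree / homoplasy census
    bootstrap_reps: int = 0
    bootstrap_seed: int | None = None
    homoplasy_methods: tuple[str, ...] = ("ml", "parsimony")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        genes = [GeneConfig(**g) for g in raw.pop("genes", [])]
        screen = raw.pop("screen", {})
        cfg = cls(
            outdir=raw.pop("outdir"),
            genotype_table=screen.get("table"),
            gene_intervals=screen.get("genes"),
            screen_strains=tuple(screen["strains"]) if "strains" in screen else None,
            screen_top_k=screen.get("top_k", 10),
            exclude_pseudogenes=screen.get("exclude_pseudogenes", False),
            genes=genes,
            groups=raw.pop("groups", None),
            guide_trees=raw.pop("guide_trees", {}),
            tree_gene=raw.pop("tree_gene", None),
            bootstrap_reps=raw.pop("bootstrap_reps", 0),
            bootstrap_seed=raw.pop("bootstrap_seed", None),
            homoplasy_methods=tuple(raw.pop("homoplasy_methods", ("ml", "parsimony"))),
        )
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cfg

    def validate(self) -> None:
        problems = []
        has_screen = self.genotype_table and self.gene_intervals and self.screen_strains
        if not has_screen and not self.genes:
            problems.append(
                "config drives no stage: provide screen inputs "
                "(table, genes, strains) and/or per-gene alignments"
            )
        if self.genes and not self.groups:
            problems.append("gene alignments given without a strain->group mapping")
        for path_attr in ("genotype_table", "gene_intervals", "groups"):
            p = getattr(self, path_attr)
            if p and not Path(p).exists():
                problems.append(f"{path_attr} file not found: {p}")
        for g in self.genes:
            if not Path(g.fasta).exists():
                problems.append(f"gene {g.gene_id} FASTA not found: {g.fasta}")
        for name, p in self.guide_trees.items():
            if not Path(p).exists():
                problems.append(f"guide tree {name!r} not found: {p}")
        if self.bootstrap_reps > 0 and self.bootstrap_seed is None:
            problems.append("bootstrap requested without a seed; seeds are mandatory")
        if problems:
            raise ValueError("invalid run config:\n- " + "\n- ".join(problems))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return (and write) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "subspecscan_version": __version__,
            "seeds": {"bootstrap": config.bootstrap_seed},
            "input_checksums": {},
        },
        "stages": {},
    }
    checksums = report["provenance"]["input_checksums"]

    def record_inputs(*paths: str | None) -> None:
        for p in paths:
            if p:
                checksums[str(p)] = _sha256(Path(p))

    # -- screen -----------------------------------------------------------
    if config.genotype_table and config.gene_intervals and config.screen_strains:
        try:
            record_inputs(config.genotype_table, config.gene_intervals)
            table = StrainGenotypeTable.from_tsv(config.genotype_table)
            genes = read_gene_intervals(config.gene_intervals)
            counts = count_differences_per_gene(
                table, config.screen_strains[0], config.screen_strains[1], genes
            )
            ranked = rank_candidates(
                counts, exclude_pseudogenes=config.exclude_pseudogenes,
                top_k=config.screen_top_k,
            )
            write_screen_report(
                rank_candidates(counts, exclude_pseudogenes=False),
                outdir / "screen_counts.tsv",
            )
            report["stages"]["screen"] = {
                "status": "ok",
                "n_genes": len(counts),
                "n_genes_with_differences": sum(1 for c in counts if c.n_differing > 0),
                "n_genes_without_differences": sum(1 for c in counts if c.n_differing == 0),
                "top_candidates": [
                    {"gene_id": c.gene_id, "n_differing": c.n_differing} for c in ranked
                ],
                "outputs": {"counts_tsv": str(outdir / "screen_counts.tsv")},
            }
        except Exception as exc:  # stage isolation is deliberate
            logger.error("screen stage failed: %s", exc)
            report["stages"]["screen"] = {"status": "failed", "error": str(exc),
                                          "trace": traceback.format_exc(limit=3)}

    # -- per-gene classification and diversity ----------------------------
    partition = None
    alignments: dict[str, MultiStrainAlignment] = {}
    if config.genes:
        try:
            record_inputs(config.groups, *[g.fasta for g in config.genes])
            partition = GroupPartition.from_tsv(config.groups)
        except Exception as exc:
            report["stages"]["classify"] = {"status": "failed", "error": str(exc)}
        if partition is not None:
            per_gene = {}
            fixed_nonsyn_sites: dict[str, list[int]] = {}
            for g in config.genes:
                try:
                    aln = MultiStrainAlignment.from_fasta(g.fasta)
                    alignments[g.gene_id] = aln
                    cls = classify_sites(aln, partition, frame_offset=g.frame_offset)
                    summary = count_categories(cls)
                    fixed_nonsyn_sites[g.gene_id] = [
                        c.site for c in cls
                        if c.category is SiteCategory.FIXED_DIFFERENCE
                        and c.coding_effect.value == "nonsynonymous"
                    ]
                    div = {}
                    for label in partition.labels:
                        members = [
                            s for s in partition.members(label) if s in aln.sequences
                        ]
                        if len(members) >= 2:
                            d = diversity(aln.subset(members))
                            div[label] = {
                                "n": d.n, "L_eff": d.L_eff, "S": d.S,
                                "pi": d.pi, "theta_w": d.theta_w,
                            }
                    cls_path = outdir / f"{g.gene_id}_sites.tsv"
                    with open(cls_path, "w") as fh:
                        fh.write("site\tcategory\talleles_A\talleles_B\tcoding_effect\n")
                        for c in cls:
                            a, b = partition.labels
                            fh.write(
                                f"{c.site}\t{c.category.value}\t"
                                f"{'/'.join(sorted(c.alleles_by_group[a]))}\t"
                                f"{'/'.join(sorted(c.alleles_by_group[b]))}\t"
                                f"{c.coding_effect.value}\n"
                            )
                    per_gene[g.gene_id] = {
                        "status": "ok", **summary, "diversity": div,
                        "outputs": {"sites_tsv": str(cls_path)},
                    }
                except Exception as exc:
                    logger.error("classify stage failed for %s: %s", g.gene_id, exc)
                    per_gene[g.gene_id] = {"status": "failed", "error": str(exc)}
            report["stages"]["classify"] = per_gene
            report["_fixed_nonsyn_sites"] = fixed_nonsyn_sites

    # -- gene tree + bootstrap --------------------------------------------
    tree_gene = config.tree_gene or (config.genes[0].gene_id if config.genes else None)
    gene_tree = None
    if tree_gene and tree_gene in alignments:
        try:
            aln = alignments[tree_gene]
            gene_tree = neighbor_joining(f84_distance_matrix(aln))
            tree_path = outdir / f"{tree_gene}_nj.nwk"
            tree_path.write_text(gene_tree.as_string(schema="newick"))
            stage = {
                "status": "ok",
                "gene_id": tree_gene,
                "clamped_branches": gene_tree.clamped_branches,
                "outputs": {"newick": str(tree_path)},
            }
            if config.bootstrap_reps > 0:
                support = bootstrap_support(
                    aln, config.bootstrap_reps, config.bootstrap_seed
                )
                stage["bootstrap"] = {
                    "n_reps": config.bootstrap_reps,
                    "supports": {
                        "|".join(sorted(s)): v for s, v in sorted(
                            support.items(), key=lambda kv: sorted(kv[0])
                        )
                    },
                }
            report["stages"]["tree"] = stage
        except Exception as exc:
            logger.error("tree stage failed: %s", exc)
            report["stages"]["tree"] = {"status": "failed", "error": str(exc)}

    # -- homoplasy census under guide trees -------------------------------
    if tree_gene and tree_gene in alignments and (config.guide_trees or gene_tree):
        import dendropy

        aln = alignments[tree_gene]
        flagged = set(report.get("_fixed_nonsyn_sites", {}).get(tree_gene, []))
        census: dict = {}
        guide_set: dict[str, dendropy.Tree] = {}
        for name, path in config.guide_trees.items():
            try:
                guide_set[name] = dendropy.Tree.get(path=path, schema="newick")
            except Exception as exc:
                census[name] = {"status": "failed", "error": str(exc)}
        if gene_tree is not None:
            guide_set.setdefault("gene_nj", gene_tree)
        for name, tree in guide_set.items():
            entry: dict = {"status": "ok"}
            for method in config.homoplasy_methods:
                try:
                    changes = ancestral_changes(tree, aln, method=method)
                    rep = detect_homoplasies(changes, flagged_sites=flagged)
                    entry[method] = {
                        "n_changes": len(changes),
                        "n_homoplasies": rep.total,
                        "n_flagged_fixed_nonsyn": rep.flagged_count,
                    }
                except Exception as exc:
                    entry[method] = {"status": "failed", "error": str(exc)}
                    entry["status"] = "partial"
            census[name] = entry
        report["stages"]["homoplasy"] = census

    # -- linkage disequilibrium -------------------------------------------
    if len(alignments) >= 2:
        try:
            gene_ids = [g.gene_id for g in config.genes if g.gene_id in alignments]
            hap = concatenate([alignments[g] for g in gene_ids], gene_ids)
            ld = r2_matrix(hap)
            hap.to_tsv(outdir / "reduced_haplotypes.tsv")
            ld.to_tsv(outdir / "ld_r2.tsv")
            summary = ld.gene_pair_summary()
            report["stages"]["ld"] = {
                "status": "ok",
                "n_sites": hap.n_sites,
                "n_multiallelic_excluded": hap.n_multiallelic_excluded,
                "gene_pairs": summary.where(summary.notna(), None).to_dict("records"),
                "outputs": {
                    "haplotypes_tsv": str(outdir / "reduced_haplotypes.tsv"),
                    "r2_tsv": str(outdir / "ld_r2.tsv"),
                },
            }
        except Exception as exc:
            logger.error("ld stage failed: %s", exc)
            report["stages"]["ld"] = {"status": "failed", "error": str(exc)}

    report.pop("_fixed_nonsyn_sites", None)
    for stage in report["stages"].values():
        for out in (stage.get("outputs") or {}).values():
            checksums[out] = _sha256(Path(out))
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
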