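"""Run every stage from one config and read the structured report.

Writes a complete synthetic input set (genotype table + gene intervals,
three gene alignments, group mapping, a species guide tree) into a
temporary directory, assembles a RunConfig, and executes screen ->
classify/diversity -> NJ tree + bootstrap -> homoplasy census -> LD.
"""

import json
import tempfile
from pathlib import Path

from subspecscan.screen import write_gene_intervals
from subspecscan.synthdata import (
    SimTableSpec,
    abpa27_like_spec,
    make_genotype_table,
    make_two_group_alignment,
    vmn1r67_like_spec,
    vmn1r71_like_spec,
)
from subspecscan.workflow import GeneConfig, RunConfig, run_pipeline

tmp = Path(tempfile.mkdtemp(prefix="subspecscan_demo_"))

table_sim = make_genotype_table(SimTableSpec(n_genes=40, seed=5))
table_sim.table.to_tsv(tmp / "genotypes.tsv")
write_gene_intervals(table_sim.genes, tmp / "genes.bed")

specs = {
    "vmn1r67": vmn1r67_like_spec(seed=2),
    "vmn1r71": vmn1r71_like_spec(seed=3),
    "abpa27": abpa27_like_spec(seed=4),
}
for gene_id, spec in specs.items():
    sim = make_two_group_alignment(spec)
    sim.alignment.to_fasta(tmp / f"{gene_id}.fasta")
sim.partition.to_tsv(tmp / "groups.tsv")
doms = ",".join(sim.partition.members("A"))
mus = ",".join(sim.partition.members("B"))
(tmp / "species.nwk").write_text(f"(({doms}),({mus}));\n")

config = RunConfig(
    outdir=str(tmp / "run"),
    genotype_table=str(tmp / "genotypes.tsv"),
    gene_intervals=str(tmp / "genes.bed"),
    screen_strains=("focalA", "focalB"),
    genes=[GeneConfig(g, str(tmp / f"{g}.fasta")) for g in specs],
    groups=str(tmp / "groups.tsv"),
    guide_trees={"species": str(tmp / "species.nwk")},
    tree_gene="vmn1r67",
    bootstrap_reps=100,
    bootstrap_seed=99,
)
report = run_pipeline(config)

print("stage status:")
for stage, info in report["stages"].items():
    status = info.get("status", "per-gene") if isinstance(info, dict) else "ok"
    print(f"  {stage}: {status}")
v67 = report["stages"]["classify"]["vmn1r67"]
print(f"\nvmn1r67: {v67['fixed_difference']} fixed "
      f"({v67['fixed_nonsynonymous']} nonsyn), "
      f"{v67['polymorphic_A']} group-A polymorphisms")
print("homoplasy census:",
      json.dumps(report["stages"]["homoplasy"], indent=2)[:400], "...")
print(f"\nfull report: {tmp / 'run' / 'report.json'}")
# Every number in report.json is re-derivable from the stage outputs written
# next to it; rerunning with the same seeds reproduces the report byte for
# byte.
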