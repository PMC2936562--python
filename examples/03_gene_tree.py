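"""Build an F84 + neighbor-joining gene tree with bootstrap support.

Evolves a 918 bp locus on a murid-scale phylogeny, estimates pairwise F84
distances, reconstructs the tree by neighbor-joining, and attaches
column-resampling bootstrap percentages to each internal split.
"""

from subspecscan.phylo import (
    bootstrap_support,
    f84_distance_matrix,
    neighbor_joining,
)
from subspecscan.synthdata import discordant_locus

aln = discordant_locus(seed=3)
D = f84_distance_matrix(aln)
print("max pairwise F84 distance:", f"{D.matrix.max():.3f}")

tree = neighbor_joining(D)
print("\nNJ gene tree (unrooted):")
print(tree.as_string(schema="newick").strip())

support = bootstrap_support(aln, n_reps=200, seed=11)
print("\nbootstrap support (200 replicates):")
for split, pct in sorted(support.items(), key=lambda kv: -kv[1]):
    print(f"  {pct:5.1f}%  {{{', '.join(sorted(split))}}}")
# Splits recovered in nearly all replicates (>95%) are robust to which
# columns happened to vary; weakly supported splits should not be
# interpreted as evidence about the locus's history.
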