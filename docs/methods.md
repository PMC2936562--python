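# Methods and design notes

## Setting and assumptions

The package analyses panels of wild-derived inbred strains: lines bred to
homozygosity from wild-caught founders of two parapatric subspecies. Two
assumptions follow and are baked into every module. First, strains are
haploid haplotypes — no heterozygote codes exist in the alphabet
(`A/C/G/T` plus `N` for missing, `-` for gaps), and linkage analysis needs
no phasing step. Second, the study design is two groups of few strains
(five per subspecies in the canonical design), so "fixed difference" is an
observation about the sampled panel, not a population-level claim; with
five haplotypes per group, a within-group variant at frequency ≤ 0.13 is
missed with probability ≥ 0.5, which is why the companion screen treats
absence of observed polymorphism cautiously.

## Site classification

A column enters the analysis only if no sequence carries `N` or a gap
there (complete deletion). This is the default convention of the standard
diversity software for this analysis and keeps the segregating-site count
S a property of the alignment rather than of a per-pair bookkeeping rule.
The per-column classification is then exact set logic: fixed difference
iff both groups are internally monomorphic with different alleles; private
polymorphism iff exactly one group varies; shared polymorphism otherwise.
A single-strain group is allowed (a warning is logged) but can never
score a within-group polymorphism.

Coding effect is assessed per fixed site against the group-A consensus
codon: the alternate codon substitutes group B's allele at that one site,
holding the other two codon positions at the A consensus. When two fixed
differences share a codon, each is therefore scored independently — a
deterministic convention where different reasonable conventions exist; a
`joint_codon` mode compares the full A and B consensus codons instead.
Codons truncated at the alignment edge or containing missing consensus
bases are reported `not_assessed`. Genes here are intron-less with coding
length divisible by 3, so `frame_offset` defaults to 0 but must be one of
{0, 1, 2}.

## Diversity

π is the mean proportion of differing retained columns over all sequence
pairs; θ_W = S / (a_n · L_eff) with a_n the (n−1)-th harmonic number. Both
are per site. S = 0 forces both to zero exactly; L_eff = 0 (everything
deleted) is an error rather than a NaN.

## F84 distances and neighbor-joining

The pairwise distance uses the F84 closed form with base frequencies
pooled empirically over the two sequences' shared unambiguous columns.
The implementation was validated against three independent routes before
being frozen: the Jukes–Cantor closed form when frequencies are equal and
transitions occur in the 1/3 proportion, the Kimura two-parameter closed
form for any transition/transversion mix at equal frequencies, and a
numerical inversion of an independently coded F84 rate matrix (solving for
the branch length whose expected transition and transversion fractions
match the observed ones). Saturated pairs — a nonpositive logarithm
argument — yield `inf` with a warning rather than a silent clamp; the
bootstrap replaces such replicate distances by ten times the largest
finite entry so a replicate is never discarded.

Neighbor-joining follows the Studier–Keppler formulation. Tie-breaking is
deterministic (minimal Q, then smallest row/column index pair), so taxon
input order cannot change the topology. Negative branch-length estimates
are clamped to zero and counted on the tree object, matching the common
practice of distance-tree software. The final tree is unrooted,
represented with a trifurcating seed node; an additive input matrix is
reproduced exactly (path distances to 1e−9), which the tests check, and
topologies agree with an independent NJ implementation on the same
matrices.

Bootstrap support resamples columns with replacement; one master seed
spawns one child RNG stream per replicate, so supports are reproducible
and individual replicates are independent.

## Ancestral reconstruction and the homoplasy census

Two reconstruction methods run on any guide tree, including
multifurcating ones (the canonical species tree carries the three-way
subspecies polytomy as a true multifurcation):

* **Parsimony** — Hartigan's generalisation of Fitch's algorithm (exact
  minimum change on multifurcating trees). The down-pass keeps the parent
  state when it lies in a node's top vote set and otherwise takes the
  alphabetically first member, a deterministic minimum-change labelling.
* **Joint ML** — the Pupko dynamic programme under an HKY model with
  empirical base frequencies (clipped away from zero) and a
  transition/transversion ratio of 2 by default. Ties resolve to the
  alphabetically first state. When the guide tree carries no branch
  lengths — topology-only species trees usually do not — a single shared
  branch length is estimated by maximising the Felsenstein pruning
  likelihood over the variable columns; this deliberately simple
  re-estimation suits a census, not branch-length inference.

The original analysis this mirrors reconstructed ancestors under a codon
model; reconstruction here is at nucleotide level, so homoplasy totals
under the two model families are similar in kind but not numerically
interchangeable, and both methods are always reported side by side.

A homoplasy is a change-type: a (site, ancestral state, derived state)
triple inferred on two or more branches. The census counts change-types,
not change-instances, following the natural reading of "identical changes
on more than one branch"; each report entry lists its branches, so an
instance count is recoverable. Entries can be flagged against a supplied
site set (e.g. the fixed nonsynonymous inter-group columns).

## Linkage disequilibrium

Each gene is reduced to columns variable among non-missing entries;
columns with more than two alleles are excluded (counted and logged), and
missing entries survive into the haplotype matrix where pairs then use
pairwise-complete rows. r² is computed from major-allele frequencies; a
site monomorphic after row removal makes the pair *undefined* (NaN),
deliberately distinct from measured independence (0). Gene pairs are
summarised by both max and mean r², because a site-level heat map and a
gene-level association claim need different summaries: between two
group-fixed genes both are 1; between a group-fixed site and a singleton
polymorphism in ten haplotypes r² is 1/9, which is what the mean against a
purely polymorphic gene settles near. No significance test runs by
default (five haplotypes per group give the Fisher exact test almost no
power); `fisher_exact_pvalues` exists for completeness.

## Synthetic data: what it emulates and what it does not

`make_two_group_alignment` injects a requested number of fixed
differences and private polymorphisms at disjoint positions into an
i.i.d. background (uniform base composition by default — none is imposed
by the design). Polymorphisms are singletons by default (`minor_count=1`),
a choice made once because the emulated design reports only polymorphism
counts, not allele frequencies. When coding-effect targets are set, fixed
sites are placed one per codon and the substitution is chosen through the
standard genetic code at construction time (stop-creating changes are
skipped), independently of the classifier that is later tested against it.
The preset specs encode the canonical study conditions: a 915 bp gene with
24 fixed differences (15 nonsynonymous, 9 synonymous) and two group-A
polymorphisms; a 921 bp gene with 35 polymorphisms and no fixed
differences, split 18/17 between the groups since only the total is
reported in the emulated design; a 1185 bp group-fixed stand-in (8 fixed
differences, a synthetic invention — its real counterpart is not
distributed with this package).

`evolve_on_tree` evolves sites independently under HKY (matrix
exponential of the scaled rate matrix per branch). The infinite-sites mode
draws Poisson mutation counts per branch and gives every mutation a fresh
column, so zero homoplasy on the generating tree holds by construction —
this is the right emulation for the guide-tree contrast, because at
shallow murid divergence real loci rarely take repeated hits, and it keeps
the species-tree census a pure discordance signal. Finite-sites mode, by
contrast, produces genuine recurrent mutation at murid branch lengths
(dozens of true homoplasies in ~900 bp), which is worth knowing when
interpreting a census on real data. The built-in discordant gene tree
places the domesticus allele inside the outgroup species — an
introgression-like history — with branch lengths chosen once at plausible
murid scale; the species-tree census total therefore scales with those
lengths and is reported as a computed quantity, not matched to any
external figure.

What the generator does **not** emulate: coalescent genealogies and
shared ancestral polymorphism, recombination within genes, indels,
rate heterogeneity across sites, base-composition bias, and realistic
array-resequencing error structure (the genotype table's `N` masking is a
plain per-call Bernoulli, since no published error model is available for
the emulated platform). Passing tests therefore demonstrate correctness of
the algorithms under the declared statistical structure, not robustness to
every property of real resequencing data.

`make_genotype_table` records, per gene, the number of SNPs left with two
unambiguous differing focal calls after masking — the quantity an honest
screen must report — so screens are tested against construction-time
truth rather than a re-implementation.

## Coordinates and formats

Genotype tables carry 1-based positions (as SNP releases do); gene
intervals are BED: 0-based, half-open, with an optional fifth column as a
pseudogene flag. A SNP at 1-based `pos` belongs to a gene iff `pos − 1 ∈
[start, end)`. Alignment sites are reported 1-based. FASTA record ids may
carry a `|groupX` suffix (written by the generator, stripped on read);
group mappings are two-column TSV. Trees are Newick via dendropy, with
multifurcations and branch lengths preserved round-trip.

## Workflow and reproducibility

The orchestrator validates its config up front (listing every missing
input at once), runs stages in dependency order, isolates stage failures,
and writes SHA-256 checksums for all inputs and outputs into the report.
Stochastic stages have no default seed — omitting the bootstrap seed is a
config error. Reports contain no timestamps, so identical configs and
seeds produce byte-identical reports; the tests assert this.

## Problem sizes

Defaults throughout are desk-scale and chosen as such: 10-strain
alignments of ~0.9–1.2 kb, a 392-gene screen table, 918 bp cross-species
loci on a 9-taxon tree, 200 bootstrap replicates in the acceptance script
(1000 is the conventional publication-grade number and runs in well under
a minute via `bootstrap_support` if wanted). The full test suite and the
acceptance script each complete in a few seconds on one CPU.

## Known limitations

* The F84 distance uses per-pair pooled empirical frequencies; very short
  or compositionally extreme pairs can saturate (reported as `inf`).
* Joint-ML reconstruction fixes κ = 2 rather than estimating it; for a
  census of recurrent changes this has little effect (parsimony, which
  uses no rates at all, agrees with ML at low divergence in the tests),
  but it is not a substitute for model fitting.
* The shared-branch-length re-estimation for length-free guide trees is a
  one-parameter profile, adequate for state reconstruction but not for
  divergence-time use.
* `variable_sites` (complete deletion) and the LD module's candidate
  columns (variable among non-missing entries) deliberately differ;
  alignments without missing data make them identical.
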