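"""Distance gene trees and ancestral-change reconstruction.

The gene tree is built the classical way: pairwise F84 nucleotide distances
(unequal base frequencies, transition/transversion distinction) feed
Saitou–Nei neighbor-joining, with nonparametric bootstrap over columns for
split support. Given any guide tree — for instance the organismal species
tree with an unresolved polytomy — ancestral states are reconstructed either
by Fitch/Hartigan parsimony or by joint maximum likelihood under an
HKY-class model, and recurrent identical changes (homoplasies) are censused.
A locus whose history departs from the species tree, through introgression
or lineage sorting, shows an excess of apparent homoplasies when the species
tree is imposed and few or none on its own gene tree.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .alignment import BASES, MISSING, MultiStrainAlignment

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# substitution model machinery (shared with the sequence simulator)
# ---------------------------------------------------------------------------

def hky_rate_matrix(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """HKY85 rate matrix in ACGT order, scaled to one expected substitution
    per site at stationarity."""
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    if kappa <= 0:
        raise ValueError("transition/transversion ratio must be positive")
    Q = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            rate = freqs[b]
            if (BASES[a], BASES[b]) in _TRANSITIONS:
                rate *= kappa
            Q[a, b] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def transition_probabilities(freqs: np.ndarray, kappa: float, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled HKY matrix; t in substitutions/site."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    return expm(hky_rate_matrix(freqs, kappa) * t)


# ---------------------------------------------------------------------------
# F84 distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])


def _pair_site_counts(s1: str, s2: str) -> tuple[int, int, int, Counter]:
    """(n_complete, n_transitions, n_transversions, pooled base counts) over
    columns where both sequences carry an unambiguous base."""
    n = ts = tv = 0
    pooled: Counter = Counter()
    for a, b in zip(s1, s2):
        if a in MISSING or b in MISSING:
            continue
        n += 1
        pooled[a] += 1
        pooled[b] += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return n, ts, tv, pooled


def f84_distance(s1: str, s2: str) -> float:
    """Pairwise F84 distance from observed transition/transversion fractions.

    Base frequencies are estimated empirically, pooled over the two
    sequences' shared unambiguous columns. With frequencies pi and purine /
    pyrimidine totals pi_R, pi_Y, the constants are

        A = pi_C pi_T / pi_Y + pi_A pi_G / pi_R
        B = pi_C pi_T + pi_A pi_G
        C = pi_R pi_Y

    and d = -2A ln(1 - P/(2A) - (A-B)Q/(2AC)) + 2(A-B-C) ln(1 - Q/(2C)).
    Saturated pairs (nonpositive log argument) return ``inf`` with a warning.
    """
    n, ts, tv, pooled = _pair_site_counts(s1, s2)
    if n == 0:
        raise ValueError("no pairwise complete columns")
    if ts == 0 and tv == 0:
        return 0.0
    P = ts / n
    Q = tv / n
    total = sum(pooled.values())
    pi = {b: pooled.get(b, 0) / total for b in BASES}
    piR = pi["A"] + pi["G"]
    piY = pi["C"] + pi["T"]
    if piR <= 0 or piY <= 0:
        logger.warning("degenerate base composition (no purines or no pyrimidines)")
        return math.inf
    A = pi["C"] * pi["T"] / piY + pi["A"] * pi["G"] / piR
    B = pi["C"] * pi["T"] + pi["A"] * pi["G"]
    C = piR * piY
    if A <= 0:
        logger.warning("degenerate composition: F84 constant A is zero")
        return math.inf
    arg1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    arg2 = 1.0 - Q / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        logger.warning("saturated pair (P=%.3f, Q=%.3f); distance set to inf", P, Q)
        return math.inf
    return -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)


def f84_distance_matrix(aln: MultiStrainAlignment) -> DistanceMatrix:
    taxa = aln.strains
    m = np.zeros((len(taxa), len(taxa)))
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            d = f84_distance(aln.sequences[taxa[i]], aln.sequences[taxa[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining with the Studier–Keppler criterion.

    Tie-break is deterministic: among minimal Q entries the smallest
    (row, col) index pair in the current matrix order is joined. Negative
    branch-length estimates are clamped to zero; the tree carries the count
    in ``tree.clamped_branches``. The result is unrooted, represented with a
    trifurcating seed node.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.all(np.isfinite(D.matrix)):
        raise ValueError("distance matrix contains non-finite entries")

    ns = dendropy.TaxonNamespace(list(D.taxa))
    nodes = [dendropy.Node(taxon=ns.get_taxon(t)) for t in D.taxa]
    d = D.matrix.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best_q = math.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q, bi, bj = q, i, j
        vi = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        vj = d[bi, bj] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[bi])
        parent.add_child(nodes[bj])
        nodes[bi].edge.length = clamp(vi)
        nodes[bj].edge.length = clamp(vj)

        new_row = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [k for k in range(m) if k != bj]
        d2 = d[np.ix_(keep, keep)]
        pos = keep.index(bi)
        new_vals = new_row[keep]
        d2[pos, :] = new_vals
        d2[:, pos] = new_vals
        d2[pos, pos] = 0.0
        d = d2
        nodes = [parent if k == bi else nodes[k] for k in keep]

    # final three-point join -> trifurcating unrooted seed
    root = dendropy.Node()
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        root.add_child(node)
        node.edge.length = clamp(length)

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    tree.clamped_branches = clamped
    if clamped:
        logger.warning("%d negative NJ branch lengths clamped to zero", clamped)
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    m = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                ta = tree.taxon_namespace.get_taxon(a)
                tb = tree.taxon_namespace.get_taxon(b)
                m[i, j] = m[j, i] = pdm.patristic_distance(ta, tb)
    return DistanceMatrix(taxa, m)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial unrooted splits, each canonicalised to the side that does
    not contain the alphabetically first taxon."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_taxa = frozenset(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else all_taxa - below
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    aln: MultiStrainAlignment, n_reps: int, seed: int
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support (percent) for the F84+NJ tree.

    One master seed; replicate RNG streams are spawned deterministically so
    the same seed always reproduces the same supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    original = neighbor_joining(f84_distance_matrix(aln))
    splits = tree_bipartitions(original)
    counts = {s: 0 for s in splits}
    L = aln.length
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    # negative-branch clamps inside replicates are routine; don't warn per rep
    rep_level = max(logger.getEffectiveLevel(), logging.ERROR)
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, L, size=L)
        resampled = MultiStrainAlignment(
            {name: "".join(seq[c] for c in cols) for name, seq in aln.sequences.items()}
        )
        D = f84_distance_matrix(resampled)
        if not np.all(np.isfinite(D.matrix)):
            # saturation in a replicate: cap at a large finite distance
            finite_max = np.nanmax(np.where(np.isfinite(D.matrix), D.matrix, np.nan))
            m = np.where(np.isfinite(D.matrix), D.matrix, 10.0 * max(finite_max, 1.0))
            np.fill_diagonal(m, 0.0)
            D = DistanceMatrix(D.taxa, m)
        prev = logger.level
        logger.setLevel(rep_level)
        try:
            rep_splits = tree_bipartitions(neighbor_joining(D))
        finally:
            logger.setLevel(prev)
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / n_reps for s, c in counts.items()}


# ---------------------------------------------------------------------------
# ancestral reconstruction and homoplasy census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchChange:
    """A single inferred substitution on one branch at one alignment column."""

    branch: str  # "parent->child" using deterministic node labels
    site: int  # 1-based alignment column
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("from_state and to_state must differ")


@dataclass(frozen=True)
class HomoplasyEntry:
    site: int
    from_state: str
    to_state: str
    branches: tuple[str, ...]
    flagged: bool = False


@dataclass(frozen=True)
class HomoplasyReport:
    entries: tuple[HomoplasyEntry, ...]

    @property
    def total(self) -> int:
        """Number of homoplastic change-types (site, from, to) on >= 2 branches."""
        return len(self.entries)

    @property
    def flagged_count(self) -> int:
        return sum(1 for e in self.entries if e.flagged)

    @property
    def sites(self) -> set[int]:
        return {e.site for e in self.entries}


def _prepare_tree(tree: dendropy.Tree, aln: MultiStrainAlignment) -> dendropy.Tree:
    work = tree.clone(depth=1)
    leaf_names = set()
    for lf in work.leaf_node_iter():
        if lf.taxon is None:
            raise ValueError("tree has an unlabeled leaf")
        leaf_names.add(lf.taxon.label)
    missing = leaf_names - set(aln.strains)
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
    k = 0
    for node in work.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"node{k}"
            k += 1
    return work


def _hartigan_site(work: dendropy.Tree, states: dict[str, str]) -> dict:
    """Minimum-change state assignment on a (possibly multifurcating) tree.

    Bottom-up pass computes each node's top vote set; top-down keeps the
    parent state when it is in the set, otherwise takes the alphabetically
    first member. Missing leaf data ({N, -}) is unconstrained.
    """
    top: dict = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.label, "N")
            top[node] = frozenset(BASES) if s in MISSING else frozenset({s})
        else:
            votes = Counter()
            for child in node.child_nodes():
                for s in top[child]:
                    votes[s] += 1
            k = max(votes.values())
            top[node] = frozenset(s for s, c in votes.items() if c == k)
    assigned: dict = {}
    for node in work.preorder_node_iter():
        options = top[node]
        if node.parent_node is None:
            assigned[node] = min(options)
        else:
            p = assigned[node.parent_node]
            assigned[node] = p if p in options else min(options)
    return assigned


def _edge_lengths_present(work: dendropy.Tree) -> bool:
    for node in work.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            return False
    return True


def _loglik_given_scale(
    work: dendropy.Tree,
    columns: list[dict[str, str]],
    freqs: np.ndarray,
    kappa: float,
    t: float,
) -> float:
    """Felsenstein-pruning log-likelihood with every edge set to length t."""
    P = transition_probabilities(freqs, kappa, t)
    logP = np.log(np.maximum(P, 1e-300))
    total = 0.0
    for col in columns:
        partial: dict = {}
        for node in work.postorder_node_iter():
            if node.is_leaf():
                s = col.get(node.label, "N")
                vec = np.zeros(4) if s not in MISSING else np.full(4, 1.0)
                if s not in MISSING:
                    vec[_BASE_INDEX[s]] = 1.0
                partial[node] = vec
            else:
                vec = np.ones(4)
                for child in node.child_nodes():
                    vec = vec * (P @ partial[child])
                partial[node] = vec
        total += math.log(max(float(freqs @ partial[work.seed_node]), 1e-300))
    return total


def _pupko_site(
    work: dendropy.Tree,
    states: dict[str, str],
    logP: dict,
    log_freqs: np.ndarray,
) -> dict:
    """Joint maximum-likelihood ancestral states (Pupko dynamic programme).

    Ties resolve to the alphabetically first state (lowest ACGT index).
    """
    best_val: dict = {}
    best_choice: dict = {}
    for node in work.postorder_node_iter():
        if node.parent_node is None:
            continue
        lp = logP[node]
        if node.is_leaf():
            s = states.get(node.label, "N")
            if s in MISSING:
                vals = lp.max(axis=1)
                choice = lp.argmax(axis=1)
            else:
                idx = _BASE_INDEX[s]
                vals = lp[:, idx]
                choice = np.full(4, idx)
        else:
            child_sum = np.zeros(4)
            for child in node.child_nodes():
                child_sum += best_val[child]
            scores = lp + child_sum[None, :]
            vals = scores.max(axis=1)
            choice = scores.argmax(axis=1)
        best_val[node] = vals
        best_choice[node] = choice

    root = work.seed_node
    root_scores = log_freqs.copy()
    for child in root.child_nodes():
        root_scores += best_val[child]
    assigned: dict = {root: BASES[int(root_scores.argmax())]}
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_idx = _BASE_INDEX[assigned[node.parent_node]]
        assigned[node] = BASES[int(best_choice[node][parent_idx])]
    return assigned


def empirical_base_frequencies(aln: MultiStrainAlignment) -> np.ndarray:
    counts = Counter()
    for seq in aln.sequences.values():
        for c in seq:
            if c in _BASE_INDEX:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("alignment has no unambiguous bases")
    return np.array([counts.get(b, 0) / total for b in BASES])


def ancestral_changes(
    tree: dendropy.Tree,
    aln: MultiStrainAlignment,
    method: str = "ml",
    kappa: float = 2.0,
) -> list[BranchChange]:
    """Per-branch substitutions from ancestral state reconstruction.

    ``method='parsimony'`` uses Fitch/Hartigan minimum change;
    ``method='ml'`` uses joint maximum likelihood under HKY with empirical
    base frequencies. Both handle multifurcating guide trees. For ML, branch
    lengths absent from the guide tree are re-estimated from the data as a
    single shared length maximising the pruning likelihood.
    """
    if method not in ("parsimony", "ml"):
        raise ValueError(f"unknown method {method!r}")
    work = _prepare_tree(tree, aln)
    leaf_names = [lf.label for lf in work.leaf_node_iter()]

    changes: list[BranchChange] = []
    sites = range(1, aln.length + 1)

    if method == "parsimony":
        for site in sites:
            col = aln.column(site)
            obs = {c for name in leaf_names if (c := col[name]) not in MISSING}
            if len(obs) < 2:
                continue
            assigned = _hartigan_site(work, col)
            for node in work.preorder_node_iter():
                if node.parent_node is None:
                    continue
                a, b = assigned[node.parent_node], assigned[node]
                if a != b:
                    changes.append(
                        BranchChange(f"{node.parent_node.label}->{node.label}", site, a, b)
                    )
        return changes

    freqs = empirical_base_frequencies(aln.subset(leaf_names))
    # a base absent from the data still needs nonzero rate mass for the model
    freqs = np.clip(freqs, 1e-6, None)
    freqs = freqs / freqs.sum()
    if not _edge_lengths_present(work):
        var_cols = []
        for site in sites:
            col = aln.column(site)
            obs = {c for name in leaf_names if (c := col[name]) not in MISSING}
            if len(obs) >= 2:
                var_cols.append(col)
        res = minimize_scalar(
            lambda t: -_loglik_given_scale(work, var_cols, freqs, kappa, t),
            bounds=(1e-4, 5.0),
            method="bounded",
        )
        t_hat = float(res.x)
        logger.info("guide tree had no branch lengths; shared ML length %.4f", t_hat)
        for node in work.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = t_hat

    logP = {}
    cache: dict[float, np.ndarray] = {}
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = max(float(node.edge.length), 1e-8)
        if t not in cache:
            cache[t] = np.log(np.maximum(transition_probabilities(freqs, kappa, t), 1e-300))
        logP[node] = cache[t]
    log_freqs = np.log(np.maximum(freqs, 1e-300))

    for site in sites:
        col = aln.column(site)
        obs = {c for name in leaf_names if (c := col[name]) not in MISSING}
        if len(obs) < 2:
            continue
        assigned = _pupko_site(work, col, logP, log_freqs)
        for node in work.preorder_node_iter():
            if node.parent_node is None:
                continue
            a, b = assigned[node.parent_node], assigned[node]
            if node.is_leaf() and col.get(node.label, "N") in MISSING:
                continue  # no observable change at a missing leaf
            if a != b:
                changes.append(
                    BranchChange(f"{node.parent_node.label}->{node.label}", site, a, b)
                )
    return changes


def detect_homoplasies(
    changes: list[BranchChange],
    flagged_sites: set[int] | None = None,
) -> HomoplasyReport:
    """Census of identical changes recurring on more than one branch.

    Changes are grouped by (site, ancestral state, derived state); a group
    spanning >= 2 branches is one homoplastic change-type. ``flagged_sites``
    (for instance the fixed nonsynonymous inter-group columns) marks entries
    whose column is of special interest.
    """
    groups: dict[tuple[int, str, str], list[str]] = defaultdict(list)
    for ch in changes:
        groups[(ch.site, ch.from_state, ch.to_state)].append(ch.branch)
    flagged_sites = flagged_sites or set()
    entries = [
        HomoplasyEntry(site, fr, to, tuple(sorted(branches)), site in flagged_sites)
        for (site, fr, to), branches in sorted(groups.items())
        if len(branches) >= 2
    ]
    return HomoplasyReport(tuple(entries))
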