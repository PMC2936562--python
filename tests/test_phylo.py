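"""F84 distances, neighbor-joining, bootstrap, and ancestral changes."""

import io
import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import fsolve

from subspecscan.alignment import BASES, MultiStrainAlignment
from subspecscan.phylo import (
    DistanceMatrix,
    ancestral_changes,
    bootstrap_support,
    detect_homoplasies,
    f84_distance,
    f84_distance_matrix,
    neighbor_joining,
    transition_probabilities,
    tree_bipartitions,
    tree_path_distances,
)
from subspecscan.synthdata import TreeSimSpec, evolve_on_tree

PURINES = {"A", "G"}


def _pair_with_counts(n_ts_each: int, n_tv_each: int, length_per_base: int = 300):
    """Sequence pair with equal pooled base frequencies, ``4*n_ts_each``
    transitions and ``4*n_tv_each`` transversions, built from symmetric
    substitution pairs so pooled composition stays uniform."""
    s1 = list("A" * length_per_base + "C" * length_per_base
              + "G" * length_per_base + "T" * length_per_base)
    s2 = s1.copy()
    cursor = {b: i * length_per_base for i, b in enumerate("ACGT")}

    def apply(pairs, k):
        for frm, to in pairs:
            for _ in range(k):
                s2[cursor[frm]] = to
                cursor[frm] += 1

    apply([("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")], n_ts_each)
    apply([("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")], n_tv_each)
    return "".join(s1), "".join(s2)


def _f84_rate_matrix(freqs, alpha, beta=1.0):
    """Independent F84 parameterisation: transversion-type rate beta*pi_b,
    plus a within-class transition boost alpha*pi_b/pi_class(b)."""
    Q = np.zeros((4, 4))
    piR = freqs[0] + freqs[2]
    piY = freqs[1] + freqs[3]
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            rate = beta * freqs[b]
            if {BASES[a], BASES[b]} <= PURINES:
                rate += alpha * freqs[b] / piR
            elif not ({BASES[a], BASES[b]} & PURINES):
                rate += alpha * freqs[b] / piY
            Q[a, b] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def _expected_ts_tv(freqs, alpha, t):
    P = expm(_f84_rate_matrix(freqs, alpha) * t)
    ts = tv = 0.0
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            same_class = ({BASES[a], BASES[b]} <= PURINES) or not (
                {BASES[a], BASES[b]} & PURINES
            )
            if same_class:
                ts += freqs[a] * P[a, b]
            else:
                tv += freqs[a] * P[a, b]
    return ts, tv


class TestF84Distance:
    def test_identical_sequences_distance_zero(self):
        assert f84_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_jukes_cantor_limit(self):
        # equal frequencies with transitions in JC proportion (1/3 of changes)
        s1, s2 = _pair_with_counts(n_ts_each=15, n_tv_each=30)
        D = (4 * 15 + 4 * 30) / len(s1)
        jc = -0.75 * math.log(1 - 4 * D / 3)
        assert f84_distance(s1, s2) == pytest.approx(jc, rel=1e-12)

    def test_kimura_two_parameter_limit(self):
        # equal frequencies, arbitrary ts/tv mix, against the K80 closed form
        s1, s2 = _pair_with_counts(n_ts_each=40, n_tv_each=10)
        P, Q = 4 * 40 / len(s1), 4 * 10 / len(s1)
        k80 = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert f84_distance(s1, s2) == pytest.approx(k80, rel=1e-12)

    def test_formula_inverts_the_f84_model(self):
        """The closed form must recover the t that makes the F84 model's
        expected transition/transversion fractions match the observed ones
        (numerical inversion of an independently coded rate matrix)."""
        rng = np.random.default_rng(3)
        s1 = "".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.3, 0.2], size=4000))
        s2 = list(s1)
        idx = rng.choice(4000, size=400, replace=False)
        for i in idx[:250]:  # transitions
            s2[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s2[i]]
        for i in idx[250:]:  # transversions
            s2[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s2[i]]
        s2 = "".join(s2)
        d_closed = f84_distance(s1, s2)

        pooled = np.zeros(4)
        ts_obs = tv_obs = 0
        for a, b in zip(s1, s2):
            pooled[BASES.index(a)] += 1
            pooled[BASES.index(b)] += 1
            if a != b:
                same_class = ({a, b} <= PURINES) or not ({a, b} & PURINES)
                ts_obs += same_class
                tv_obs += not same_class
        freqs = pooled / pooled.sum()
        P_obs, Q_obs = ts_obs / len(s1), tv_obs / len(s1)

        def residual(params):
            t, alpha = params
            ts, tv = _expected_ts_tv(freqs, abs(alpha), abs(t))
            return [ts - P_obs, tv - Q_obs]

        (t_hat, _), info, ok, _ = fsolve(residual, [0.1, 1.0], full_output=True)
        assert ok == 1
        assert d_closed == pytest.approx(abs(t_hat), rel=1e-6)

    def test_simulated_pair_recovers_known_divergence(self):
        L, t_true = 100_000, 0.1
        aln = evolve_on_tree(
            TreeSimSpec(tree=f"(x:0.0,y:{t_true});", length=L, kappa=2.0, seed=5)
        )
        d = f84_distance(aln.sequences["x"], aln.sequences["y"])
        p = sum(1 for u, v in zip(aln.sequences["x"], aln.sequences["y"]) if u != v) / L
        se_d = math.sqrt(p * (1 - p) / L) / (1 - 4 * p / 3)  # delta-method scale
        assert abs(d - t_true) < 3 * se_d

    def test_saturation_reports_infinite_distance(self, caplog):
        s1 = "A" * 50 + "C" * 50 + "G" * 50 + "T" * 50
        s2 = "G" * 50 + "T" * 50 + "A" * 50 + "C" * 50  # all transitions
        with caplog.at_level("WARNING"):
            assert math.isinf(f84_distance(s1, s2))


def _splits_from_newick(nwk):
    return tree_bipartitions(dendropy.Tree.get(data=nwk, schema="newick"))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(["a", "b", "c"], np.array(
            [[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]]
        ))
        tree = neighbor_joining(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["c"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)

    def test_additive_matrix_recovered_exactly(self):
        nwk = "((a:0.11,b:0.23):0.05,(c:0.07,d:0.02):0.09,e:0.31);"
        source = dendropy.Tree.get(data=nwk, schema="newick")
        D = tree_path_distances(source)
        tree = neighbor_joining(D)
        assert tree_bipartitions(tree) == tree_bipartitions(source)
        D2 = tree_path_distances(tree)
        idx = [D2.taxa.index(t) for t in D.taxa]
        assert np.abs(D.matrix - D2.matrix[np.ix_(idx, idx)]).max() < 1e-9

    def test_agrees_with_dendropy_reference_nj(self):
        nwk = "((t1:0.10,t2:0.14):0.05,(t3:0.08,(t4:0.06,t5:0.09):0.04):0.03,t6:0.20);"
        aln = evolve_on_tree(TreeSimSpec(tree=nwk, length=2000, seed=11))
        D = f84_distance_matrix(aln)
        ours = neighbor_joining(D)

        csv = "," + ",".join(D.taxa) + "\n" + "\n".join(
            t + "," + ",".join(f"{D.matrix[i, j]:.10f}" for j in range(len(D.taxa)))
            for i, t in enumerate(D.taxa)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        reference = pdm.nj_tree()
        assert tree_bipartitions(ours) == tree_bipartitions(reference)

    def test_taxon_order_does_not_change_topology(self):
        nwk = "((a:0.1,b:0.2):0.06,(c:0.07,d:0.03):0.04,(e:0.2,f:0.1):0.02);"
        D = tree_path_distances(dendropy.Tree.get(data=nwk, schema="newick"))
        perm = [3, 0, 5, 1, 4, 2]
        D_perm = DistanceMatrix(
            [D.taxa[i] for i in perm], D.matrix[np.ix_(perm, perm)]
        )
        assert tree_bipartitions(neighbor_joining(D)) == tree_bipartitions(
            neighbor_joining(D_perm)
        )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_fewer_than_three_taxa_rejected(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(D)


class TestBootstrap:
    def _alignment(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), size=400))
        seqs = {}
        for i, name in enumerate(["out", "x1", "x2", "y1", "y2"]):
            s = list(base)
            for j in range(i * 30, i * 30 + 25):
                s[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[j]]
            seqs[name] = "".join(s)
        seqs["x2"] = seqs["x1"]  # identical pair -> guaranteed bipartition
        return MultiStrainAlignment(seqs)

    def test_identical_sequence_pair_has_full_support(self):
        support = bootstrap_support(self._alignment(), n_reps=20, seed=4)
        assert support[frozenset({"x1", "x2"})] == 100.0

    def test_single_replicate_supports_are_all_or_nothing(self):
        support = bootstrap_support(self._alignment(), n_reps=1, seed=9)
        assert set(support.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        a = bootstrap_support(self._alignment(), n_reps=25, seed=31)
        b = bootstrap_support(self._alignment(), n_reps=25, seed=31)
        assert a == b


class TestAncestralChanges:
    QUARTET = "((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);"

    def _aln(self, cols):
        """Build an alignment from per-taxon strings of equal length."""
        return MultiStrainAlignment(cols)

    def test_invariant_columns_produce_no_changes(self):
        tree = dendropy.Tree.get(data=self.QUARTET, schema="newick")
        aln = self._aln({"a": "AAAA", "b": "AAAA", "c": "AAAA", "d": "AAAA"})
        for method in ("parsimony", "ml"):
            assert ancestral_changes(tree, aln, method=method) == []

    def test_clean_split_implies_single_internal_change(self):
        tree = dendropy.Tree.get(data=self.QUARTET, schema="newick")
        aln = self._aln({"a": "T", "b": "T", "c": "C", "d": "C"})
        changes = ancestral_changes(tree, aln, method="parsimony")
        assert len(changes) == 1
        assert {changes[0].from_state, changes[0].to_state} == {"T", "C"}

    def test_conflicting_split_yields_one_homoplastic_change_type(self):
        tree = dendropy.Tree.get(data=self.QUARTET, schema="newick")
        aln = self._aln({"a": "T", "b": "C", "c": "T", "d": "C"})
        changes = ancestral_changes(tree, aln, method="parsimony")
        report = detect_homoplasies(changes)
        assert report.total == 1
        assert len(report.entries[0].branches) == 2

    def test_leaf_missing_from_alignment_is_an_error(self):
        tree = dendropy.Tree.get(data=self.QUARTET, schema="newick")
        aln = self._aln({"a": "T", "b": "C", "c": "T"})
        with pytest.raises(ValueError, match="missing"):
            ancestral_changes(tree, aln, method="parsimony")

    def test_multifurcating_guide_tree_is_supported(self):
        tree = dendropy.Tree.get(
            data="((a:0.05,b:0.05,c:0.05):0.02,(d:0.05,e:0.05):0.02);",
            schema="newick",
        )
        aln = self._aln({n: s for n, s in zip("abcde", ["T", "T", "T", "C", "C"])})
        for method in ("parsimony", "ml"):
            changes = ancestral_changes(tree, aln, method=method)
            assert len(changes) == 1

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_parsimony_and_ml_agree_at_low_divergence(self, seed):
        nwk = "((a:0.02,b:0.03):0.01,(c:0.02,d:0.01):0.015,e:0.03);"
        aln = evolve_on_tree(TreeSimSpec(tree=nwk, length=3000, seed=seed))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        n_pars = len(ancestral_changes(tree, aln, method="parsimony"))
        n_ml = len(ancestral_changes(tree, aln, method="ml"))
        assert n_pars == n_ml

    def test_ml_reestimates_missing_branch_lengths(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        aln = evolve_on_tree(
            TreeSimSpec(tree=self.QUARTET, length=1000, seed=3)
        )
        changes = ancestral_changes(tree, aln, method="ml")
        assert len(changes) > 0  # runs, and finds the simulated divergence

    def test_homoplasy_census_ignores_taxon_input_order(self):
        nwk = "((a:0.04,b:0.05):0.02,(c:0.03,d:0.05):0.02,e:0.08);"
        aln = evolve_on_tree(TreeSimSpec(tree=nwk, length=2000, seed=13))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        shuffled = MultiStrainAlignment(
            {k: aln.sequences[k] for k in ["e", "c", "a", "d", "b"]}
        )
        for method in ("parsimony", "ml"):
            t1 = detect_homoplasies(ancestral_changes(tree, aln, method=method)).total
            t2 = detect_homoplasies(ancestral_changes(tree, shuffled, method=method)).total
            assert t1 == t2


class TestHomoplasyReport:
    def test_flagged_sites_are_marked(self):
        tree = dendropy.Tree.get(
            data="((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);", schema="newick"
        )
        aln = MultiStrainAlignment({"a": "TA", "b": "CA", "c": "TA", "d": "CA"})
        changes = ancestral_changes(tree, aln, method="parsimony")
        report = detect_homoplasies(changes, flagged_sites={1})
        assert report.total == 1
        assert report.flagged_count == 1
        assert report.sites == {1}

    def test_unknown_method_rejected(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        aln = MultiStrainAlignment({"a": "T", "b": "C", "c": "T", "d": "C"})
        with pytest.raises(ValueError, match="method"):
            ancestral_changes(tree, aln, method="bayes")
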