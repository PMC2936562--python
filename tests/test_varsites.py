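"""Site classification, coding effect, and diversity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subspecscan.alignment import GroupPartition, MultiStrainAlignment
from subspecscan.varsites import (
    CodingEffect,
    SiteCategory,
    classify_sites,
    coding_effect,
    count_categories,
    diversity,
    harmonic_number,
    included_columns,
    variable_sites,
)

from conftest import random_alignment


class TestVariableSites:
    def test_identical_sequences_have_no_variable_sites(self):
        aln = MultiStrainAlignment({"x": "ACGTACGT", "y": "ACGTACGT"})
        assert variable_sites(aln) == []

    def test_columns_with_missing_data_are_completely_deleted(self, tiny_alignment):
        # site 10 varies among non-missing entries but carries an N
        assert 10 not in included_columns(tiny_alignment)
        assert variable_sites(tiny_alignment) == [4, 7]

    def test_gap_columns_are_excluded(self):
        aln = MultiStrainAlignment({"x": "A-GT", "y": "ACGA"})
        assert variable_sites(aln) == [4]


class TestClassification:
    def test_fixed_and_private_polymorphic_categories(self, tiny_alignment, tiny_partition):
        cls = {c.site: c.category for c in classify_sites(tiny_alignment, tiny_partition)}
        assert cls == {4: SiteCategory.FIXED_DIFFERENCE, 7: SiteCategory.POLYMORPHIC_A}

    def test_shared_polymorphism_is_polymorphic_both(self):
        aln = MultiStrainAlignment(
            {"a1": "AAAA", "a2": "AAAT", "b1": "AAAA", "b2": "AAAT"}
        )
        part = GroupPartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        (c,) = classify_sites(aln, part)
        assert c.category is SiteCategory.POLYMORPHIC_BOTH

    def test_categories_partition_the_variable_sites(self, rng):
        aln = random_alignment(rng, n=8, length=80)
        part = GroupPartition(
            {s: ("A" if i < 4 else "B") for i, s in enumerate(aln.strains)}
        )
        cls = classify_sites(aln, part)
        assert sorted(c.site for c in cls) == variable_sites(aln)
        assert len({c.site for c in cls}) == len(cls)

    def test_group_relabeling_swaps_private_polymorphism_labels(self, rng):
        aln = random_alignment(rng, n=6, length=120)
        part = GroupPartition(
            {s: ("A" if i < 3 else "B") for i, s in enumerate(aln.strains)}
        )
        direct = count_categories(classify_sites(aln, part))
        flipped = count_categories(classify_sites(aln, part.swapped()))
        assert flipped["fixed_difference"] == direct["fixed_difference"]
        assert flipped["polymorphic_A"] == direct["polymorphic_B"]
        assert flipped["polymorphic_B"] == direct["polymorphic_A"]
        assert flipped["polymorphic_both"] == direct["polymorphic_both"]

    def test_duplicating_a_sequence_never_creates_a_fixed_difference(self, rng):
        aln = random_alignment(rng, n=6, length=100)
        part = GroupPartition(
            {s: ("A" if i < 3 else "B") for i, s in enumerate(aln.strains)}
        )
        before = count_categories(classify_sites(aln, part))
        dup = MultiStrainAlignment({**aln.sequences, "copy": aln.sequences["s0"]})
        part2 = GroupPartition({**part.assignment, "copy": "A"})
        after = count_categories(classify_sites(dup, part2))
        assert after["fixed_difference"] <= before["fixed_difference"]

    def test_singleton_group_is_permitted_with_warning(self, caplog):
        aln = MultiStrainAlignment({"a1": "AAAA", "b1": "AATA", "b2": "AAAA"})
        part = GroupPartition({"a1": "A", "b1": "B", "b2": "B"})
        with caplog.at_level("WARNING"):
            cls = classify_sites(aln, part)
        assert [c.category for c in cls] == [SiteCategory.POLYMORPHIC_B]
        assert "single strain" in caplog.text


class TestCodingEffect:
    @pytest.mark.parametrize(
        "codon_a, alt, offset_in_codon, expected",
        [
            ("GGA", "G", 2, CodingEffect.SYNONYMOUS),   # GGA->GGG, glycine 4-fold
            ("ATG", "C", 0, CodingEffect.NONSYNONYMOUS),  # ATG->CTG, Met->Leu
        ],
    )
    def test_standard_code_lookup(self, codon_a, alt, offset_in_codon, expected):
        codon_b = codon_a[:offset_in_codon] + alt + codon_a[offset_in_codon + 1:]
        aln = MultiStrainAlignment(
            {"a1": codon_a, "a2": codon_a, "b1": codon_b, "b2": codon_b}
        )
        part = GroupPartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert coding_effect(aln, part, offset_in_codon + 1, 0) == expected

    def test_truncated_codon_is_not_assessed(self):
        aln = MultiStrainAlignment({"a1": "ACGTA", "b1": "ACGTG"})
        part = GroupPartition({"a1": "A", "b1": "B"})
        assert coding_effect(aln, part, 5, 0) is CodingEffect.NOT_ASSESSED

    def test_missing_consensus_base_is_not_assessed(self):
        aln = MultiStrainAlignment({"a1": "ANA", "b1": "ANC"})
        part = GroupPartition({"a1": "A", "b1": "B"})
        assert coding_effect(aln, part, 3, 0) is CodingEffect.NOT_ASSESSED

    def test_bad_frame_rejected(self, tiny_alignment, tiny_partition):
        with pytest.raises(ValueError):
            coding_effect(tiny_alignment, tiny_partition, 4, 3)


def _pi_column_oracle(aln):
    """Independent pi: per-column expected heterozygosity between random
    pairs, summed over included columns (closed form, not pairwise loops)."""
    cols = included_columns(aln)
    seqs = list(aln.sequences.values())
    n = len(seqs)
    total = 0.0
    for i in cols:
        from collections import Counter

        counts = Counter(s[i - 1] for s in seqs)
        same_pairs = sum(c * (c - 1) / 2 for c in counts.values())
        total += 1.0 - same_pairs / (n * (n - 1) / 2)
    return total / len(cols)


class TestDiversity:
    def test_monomorphic_group_has_zero_pi_and_theta(self):
        aln = MultiStrainAlignment({f"s{i}": "ACGTAC" for i in range(5)})
        d = diversity(aln)
        assert d.S == 0 and d.pi == 0.0 and d.theta_w == 0.0

    def test_two_sequences_one_difference(self):
        aln = MultiStrainAlignment({"x": "A" * 100, "y": "A" * 99 + "T"})
        d = diversity(aln)
        assert d.pi == pytest.approx(0.01, abs=0)
        assert d.theta_w == pytest.approx(0.01, abs=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pi_matches_column_heterozygosity_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=5, length=50, alphabet="ACGTN")
        if not included_columns(aln):
            return
        d = diversity(aln)
        assert d.pi == pytest.approx(_pi_column_oracle(aln), abs=1e-12)

    def test_theta_recovers_segregating_site_count(self, rng):
        aln = random_alignment(rng, n=7, length=90)
        d = diversity(aln)
        assert round(d.theta_w * d.a_n * d.L_eff) == d.S
        assert d.a_n == pytest.approx(harmonic_number(7), abs=0)

    def test_all_columns_missing_is_an_error(self):
        aln = MultiStrainAlignment({"x": "NNN", "y": "ACG"})
        with pytest.raises(ValueError, match="complete deletion"):
            diversity(aln)
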