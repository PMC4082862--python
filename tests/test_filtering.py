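import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcregress import (
    FilterPolicy,
    accept_proteins,
    filter_psms,
    group_presence_filter,
    longest_consecutive_run,
    passes_xcorr,
)
from spcregress.simulate import _independent_accept

from conftest import make_psm, random_psms


@pytest.mark.parametrize(
    "charge,xcorr,expected",
    [
        (2, 1.9, True),   # inclusive boundary at z=2
        (2, 1.89, False),
        (3, 2.3, True),
        (3, 2.29, False),
        (4, 2.6, True),
        (5, 2.6, True),   # z>=4 share one threshold
        (4, 2.59, False),
        (1, 1.9, True),   # z=1 gated like z=2
    ],
)
def test_xcorr_gate_by_charge(policy, charge, xcorr, expected):
    assert passes_xcorr(make_psm(charge=charge, xcorr=xcorr), policy) is expected


class TestConsecutiveRun:
    @pytest.mark.parametrize(
        "indices,expected",
        [({1, 2, 3, 7}, 3), (set(), 0), ({2, 4, 5, 6, 9, 10}, 3), ({5}, 1)],
    )
    def test_known_runs(self, indices, expected):
        assert longest_consecutive_run(indices) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.sets(st.integers(min_value=1, max_value=30), max_size=15))
    def test_matches_brute_force(self, indices):
        # oracle: test every candidate run start/length explicitly
        best = 0
        for start in range(1, 32):
            length = 0
            while start + length in indices:
                length += 1
            best = max(best, length)
        assert longest_consecutive_run(indices) == best


class TestFilterPsms:
    def test_occurrence_rule_removes_rare_pairs(self, policy):
        # hand-built: peptide seen twice in s1 (below the 3-occurrence rule),
        # another seen three times; all pass xcorr/length/ions
        twice = [make_psm(accession="A", peptide="ACDEFGH", b_ions={1, 2, 3})
                 for _ in range(2)]
        thrice = [make_psm(accession="B", peptide="ACDEFGHIK", y_ions={2, 3, 4})
                  for _ in range(3)]
        kept, audit = filter_psms(twice + thrice, policy, strict_paper_mode=False)
        assert {p.accession for p in kept} == {"B"}
        assert audit["occurrence"] == 2 and audit["kept"] == 3

    def test_short_peptide_rejected_despite_perfect_ions(self, policy):
        psm = make_psm(peptide="ACDEFG", b_ions={1, 2, 3, 4, 5}, y_ions={1, 2, 3, 4, 5})
        kept, audit = filter_psms([psm], policy, strict_paper_mode=False)
        assert kept == [] and audit["length"] == 1

    def test_empty_input(self, policy):
        kept, audit = filter_psms([], policy)
        assert kept == [] and all(v == 0 for v in audit.values())

    def test_strict_mode_applies_only_xcorr(self, policy):
        psm = make_psm(peptide="ACDEFG", xcorr=2.0)  # short, no ions
        kept, _ = filter_psms([psm], policy, strict_paper_mode=True)
        assert kept == [psm]

    def test_audit_conservation_random(self, policy):
        rng = np.random.default_rng(11)
        for _ in range(10):
            psms = random_psms(rng)
            for strict in (True, False):
                kept, audit = filter_psms(psms, policy, strict_paper_mode=strict)
                rejected = sum(v for k, v in audit.items() if k != "kept")
                assert len(kept) + rejected == len(psms)
                assert audit["kept"] == len(kept)

    def test_monotone_in_xcorr_threshold(self):
        rng = np.random.default_rng(5)
        psms = random_psms(rng, n=80)
        sizes = []
        for thr in (1.6, 1.9, 2.2, 2.5, 2.8):
            pol = FilterPolicy(xcorr_by_charge={"2": thr, "3": thr + 0.4, "4plus": thr + 0.7})
            kept, _ = filter_psms(psms, pol)
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)


class TestAcceptProteins:
    def test_two_unique_peptides_accepted_even_with_short_one(self, policy):
        psms = [
            make_psm(accession="A", peptide="ACDEFGHIK", b_ions={1, 2, 3}),
            make_psm(accession="A", peptide="ACDEFG"),  # short but irrelevant
        ]
        accepted = accept_proteins(psms, policy)
        assert len(accepted) == 1
        assert accepted[0].single_peptide_flag is False
        assert accepted[0].spc_by_sample == {"s1": 2}

    def test_single_peptide_needs_three_occurrences(self, policy):
        # twice in every sample: never reaches 3 in one sample
        psms = [make_psm(sample=s, accession="A", peptide="ACDEFGH", b_ions={1, 2, 3})
                for s in ("s1", "s2") for _ in range(2)]
        assert accept_proteins(psms, policy) == []
        psms3 = psms + [make_psm(sample="s1", accession="A", peptide="ACDEFGH",
                                 b_ions={1, 2, 3})]
        accepted = accept_proteins(psms3, policy)
        assert len(accepted) == 1 and accepted[0].blast_confirmation_pending

    def test_no_psms(self, policy):
        assert accept_proteins([], policy) == []

    def test_matches_independent_oracle_on_random_instances(self, policy):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            psms = random_psms(rng, n=50)
            kept, _ = filter_psms(psms, policy)
            got = {p.accession for p in accept_proteins(kept, policy)}
            assert got == _independent_accept(psms, policy)

    def test_monotone_in_occurrence_threshold(self, policy):
        rng = np.random.default_rng(21)
        psms = random_psms(rng, n=80)
        kept, _ = filter_psms(psms, policy)
        sizes = []
        for occ in (1, 2, 3, 4):
            pol = dataclasses.replace(policy, min_occurrences_per_sample=occ)
            sizes.append(len(accept_proteins(kept, pol)))
        assert sizes == sorted(sizes, reverse=True)


class TestGroupPresence:
    labels = {f"r{i}": "regression" for i in range(10)}
    labels.update({f"p{i}": "persistence" for i in range(10)})

    def prot(self, spc):
        from spcregress import AcceptedProtein

        return AcceptedProtein(accession="A", unique_peptides={"ACDEFGH"},
                               spc_by_sample=spc, single_peptide_flag=True)

    def test_three_of_ten_in_one_group_kept(self, policy):
        p = self.prot({"r0": 1, "r1": 2, "r2": 1})
        assert group_presence_filter([p], self.labels, policy) == [p]

    def test_two_of_ten_in_both_groups_dropped(self, policy):
        p = self.prot({"r0": 1, "r1": 1, "p0": 1, "p1": 1})
        assert group_presence_filter([p], self.labels, policy) == []

    def test_full_presence_at_fraction_one(self, policy):
        pol = dataclasses.replace(policy, min_group_presence_fraction=1.0)
        p = self.prot({s: 1 for s in self.labels})
        assert group_presence_filter([p], self.labels, pol) == [p]

    def test_unlabelled_sample_raises(self, policy):
        p = self.prot({"unknown": 2})
        with pytest.raises(ValueError, match="unknown"):
            group_presence_filter([p], self.labels, policy)
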