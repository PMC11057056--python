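"""Orthogroup curation rules: taxon coverage, paralog splitting, length
outliers, alignment-length gate, closest-ortholog choice."""

import pytest

from sawselect.codonalign import CodonAlignment
from sawselect.orthofilter import (
    Orthogroup,
    OrthoMember,
    filter_length_outliers,
    filter_taxon_coverage,
    min_alignment_length_filter,
    pick_closest_ortholog,
    split_paralogs,
)
from sawselect.synthetic import simulate_orthogroup_collection

TAXA = ("L_menadoensis", "C_milii", "S_retifer", "L_erinacea", "P_pectinata")


def _member(taxon, seq_id, length=100, annotation=None):
    return OrthoMember(taxon=taxon, seq_id=seq_id, protein="A" * length,
                       cds="GCT" * length, annotation=annotation)


def _group(gid, taxa=TAXA, **kw):
    return Orthogroup(group_id=gid, members=[_member(t, f"{gid}_{t}", **kw) for t in taxa])


class TestTaxonCoverage:
    def test_missing_taxon_dropped(self):
        incomplete = _group("g1", taxa=tuple(t for t in TAXA if t != "L_erinacea"))
        assert filter_taxon_coverage([incomplete], TAXA) == []

    def test_one_member_per_taxon_kept(self):
        g = _group("g1")
        assert filter_taxon_coverage([g], TAXA) == [g]

    def test_matches_ground_truth_flags(self):
        groups = simulate_orthogroup_collection(
            100, TAXA, missing_taxon_rate=0.4, seed=3
        )
        survivors = {g.group_id for g in filter_taxon_coverage(groups, TAXA)}
        expected = {g.group_id for g in groups if not g.ground_truth["missing_taxon"]}
        assert survivors == expected


class TestSplitParalogs:
    def test_two_labels_two_subgroups(self):
        g = Orthogroup("g1", [
            _member("P_pectinata", "a", annotation="A"),
            _member("L_erinacea", "b", annotation="A"),
            _member("P_pectinata", "c", annotation="B"),
        ])
        subs = split_paralogs(g)
        assert sorted(len(s.members) for s in subs) == [1, 2]
        assert all(s.group_id.startswith("g1|") for s in subs)

    def test_uniform_labels_return_group_whole(self):
        g = _group("g1", annotation="same")
        assert split_paralogs(g) == [g]

    def test_partition_matches_label_grouping_oracle(self, rng):
        labels = [str(rng.integers(0, 4)) for _ in range(20)]
        g = Orthogroup("g1", [
            _member("t", f"s{i}", annotation=lab) for i, lab in enumerate(labels)
        ])
        subs = split_paralogs(g)
        assert sum(len(s.members) for s in subs) == len(g.members)
        for s in subs:
            anns = {m.annotation for m in s.members}
            assert len(anns) == 1

    def test_unlabelled_members_form_residual_subgroup(self):
        g = Orthogroup("g1", [
            _member("t", "a", annotation="A"), _member("t", "b", annotation=None)
        ])
        subs = split_paralogs(g)
        assert len(subs) == 2


class TestLengthOutliers:
    def test_deviation_within_100_kept(self):
        g = Orthogroup("g", [_member("a", "a", 300), _member("b", "b", 300),
                             _member("c", "c", 401)])
        kept, removed = filter_length_outliers(g)
        assert len(kept.members) == 3 and removed == []

    def test_mean_computed_once_over_prefilter_group(self):
        # (200, 200, 301): all within 100 of the mean 233.67
        g = Orthogroup("g", [_member("a", "a", 200), _member("b", "b", 200),
                             _member("c", "c", 301)])
        kept, removed = filter_length_outliers(g)
        assert len(kept.members) == 3
        # adding a 500-residue member shifts the mean once, to 325.25;
        # only the 500-residue member deviates by more than 100
        g2 = Orthogroup("g", [_member("a", "a", 250), _member("b", "b", 250),
                              _member("c", "c", 301), _member("d", "d", 500)])
        kept2, removed2 = filter_length_outliers(g2)
        assert [m.seq_id for m in removed2] == ["d"]
        assert len(kept2.members) == 3

    def test_single_member_always_kept(self):
        g = Orthogroup("g", [_member("a", "a", 42)])
        kept, removed = filter_length_outliers(g)
        assert len(kept.members) == 1 and not removed

    def test_strictly_more_than_boundary(self):
        # deviations of exactly max_delta are kept ("more than" discards)
        g = Orthogroup("g", [_member("a", "a", 100), _member("b", "b", 300)])
        kept, _ = filter_length_outliers(g, max_delta_aa=100)
        assert len(kept.members) == 2

    def test_member_order_invariance(self):
        members = [_member("a", "a", 200), _member("b", "b", 310), _member("c", "c", 430)]
        ids = lambda g: sorted(m.seq_id for m in g.members)  # noqa: E731
        kept_fwd, _ = filter_length_outliers(Orthogroup("g", members))
        kept_rev, _ = filter_length_outliers(Orthogroup("g", members[::-1]))
        assert ids(kept_fwd) == ids(kept_rev)


class TestAlignmentLengthGate:
    @pytest.mark.parametrize("n_codons,passes", [(20, False), (21, True), (0, False)])
    def test_strict_threshold(self, n_codons, passes):
        aln = CodonAlignment(ids=["a", "b"], rows=["GCT" * n_codons] * 2)
        assert min_alignment_length_filter(aln, 20) is passes


class TestPickClosestOrtholog:
    MSA = {
        "focal": "MKT-LV",
        "same": "MKT-LV",
        "close": "MKTALV",
        "far": "MQSAQV",
    }

    def test_identical_candidate_chosen_with_identity_one(self):
        chosen, ident = pick_closest_ortholog("focal", ["same", "far"], self.MSA)
        assert chosen == "same" and ident == 1.0

    def test_higher_identity_wins(self):
        chosen, _ = pick_closest_ortholog("focal", ["close", "far"], self.MSA)
        assert chosen == "close"

    def test_equal_identity_breaks_ties_lexicographically(self):
        msa = {"focal": "MKTLV", "b_cand": "MKTLA", "a_cand": "MKTLA"}
        chosen, _ = pick_closest_ortholog("focal", ["b_cand", "a_cand"], msa)
        assert chosen == "a_cand"

    def test_no_candidates_raises(self):
        with pytest.raises(ValueError):
            pick_closest_ortholog("focal", [], self.MSA)


class TestGroundTruthAgreement:
    """With defect rates 0 or 1, filter outcomes follow the planted flags
    exactly."""

    def test_all_rates_zero_everything_passes(self):
        groups = simulate_orthogroup_collection(50, TAXA, seed=1)
        assert len(filter_taxon_coverage(groups, TAXA)) == 50
        for g in groups:
            assert split_paralogs(g) == [g]
            kept, removed = filter_length_outliers(g)
            assert not removed

    def test_missing_rate_one_nothing_survives(self):
        groups = simulate_orthogroup_collection(50, TAXA, missing_taxon_rate=1.0, seed=2)
        assert filter_taxon_coverage(groups, TAXA) == []

    def test_paralog_rate_one_every_group_splits(self):
        groups = simulate_orthogroup_collection(50, TAXA, paralog_rate=1.0, seed=3)
        for g in groups:
            assert len(split_paralogs(g)) == 2

    def test_outlier_rate_one_every_group_loses_one_member(self):
        groups = simulate_orthogroup_collection(50, TAXA, length_outlier_rate=1.0, seed=4)
        for g in groups:
            _, removed = filter_length_outliers(g)
            assert len(removed) == 1
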