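import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybdiag.diagnostics import (
    BETWEEN_GROUPS,
    HET_AB,
    HOM_A,
    HOM_B,
    OTHER,
    OVERALL,
    DiagnosticSite,
    DiagnosticSiteSet,
    detect_het_sites,
    find_fixed_differences,
    mean_p_distance,
    p_distance,
    zygosity_profile,
)
from hybdiag.errors import ConfigurationError, UndefinedDistanceError
from hybdiag.seq_io import AlignedSeq, Alignment, PARENTAL_A, PARENTAL_B, SampleMeta
from hybdiag.synthetic_data import coi_haplotype_sequences


def _dataset(group_a, group_b, locus="L"):
    seqs, meta = [], []
    for i, s in enumerate(group_a):
        seqs.append(AlignedSeq(f"a{i}", locus, s))
        meta.append(SampleMeta(f"a{i}", PARENTAL_A))
    for i, s in enumerate(group_b):
        seqs.append(AlignedSeq(f"b{i}", locus, s))
        meta.append(SampleMeta(f"b{i}", PARENTAL_B))
    return Alignment(locus=locus, seqs=tuple(seqs)), meta


def _bruteforce_fixed(group_a, group_b):
    """Independent per-column oracle for fixed differences."""
    out = []
    for pos in range(1, len(group_a[0]) + 1):
        col_a = {s[pos - 1] for s in group_a}
        col_b = {s[pos - 1] for s in group_b}
        if (
            len(col_a) == 1
            and len(col_b) == 1
            and col_a <= set("ACGT")
            and col_b <= set("ACGT")
            and col_a != col_b
        ):
            out.append(pos)
    return out


class TestFindFixedDifferences:
    def test_coi_fixture_four_sites(self, coi_aln, coi_meta):
        ds = find_fixed_differences(coi_aln, coi_meta)
        assert ds.positions == (40, 103, 271, 361)
        assert [(s.state_a, s.state_b) for s in ds] == [
            ("G", "A"), ("T", "C"), ("A", "T"), ("C", "T"),
        ]

    def test_no_fixed_split_locus_is_empty(self, full_fixture):
        alignments, meta, _ = full_fixture
        ds = find_fixed_differences(alignments["RPS5"], meta)
        assert len(ds) == 0

    def test_nuclear_fixture_positions(self, full_fixture):
        alignments, meta, _ = full_fixture
        assert find_fixed_differences(alignments["Wg"], meta).positions == (213, 271)
        assert find_fixed_differences(alignments["CaATP"], meta).positions == (151, 334)

    def test_minimal_example(self):
        aln, meta = _dataset(["AAAA"], ["AAAT"])
        ds = find_fixed_differences(aln, meta)
        assert [(s.position, s.state_a, s.state_b) for s in ds] == [(4, "A", "T")]

    def test_empty_group_rejected(self):
        aln = Alignment("L", (AlignedSeq("a0", "L", "ACGT"),))
        with pytest.raises(ConfigurationError):
            find_fixed_differences(aln, [SampleMeta("a0", PARENTAL_A)])

    def test_query_samples_ignored(self):
        aln, meta = _dataset(["AAAA"], ["AAAT"])
        seqs = aln.seqs + (AlignedSeq("q", "L", "CCCC"),)
        meta = meta + [SampleMeta("q", "query")]
        ds = find_fixed_differences(Alignment("L", seqs), meta)
        assert ds.positions == (4,)

    def test_ambiguity_in_parental_group_disqualifies(self):
        aln, meta = _dataset(["AAAA", "AAAA"], ["AAAW", "AAAT"])
        assert find_fixed_differences(aln, meta).positions == ()

    def test_permutation_and_duplication_invariance(self):
        rng = random.Random(7)
        a = ["".join(rng.choice("ACGT") for _ in range(30)) for _ in range(4)]
        b = ["".join(rng.choice("ACGT") for _ in range(30)) for _ in range(5)]
        aln, meta = _dataset(a, b)
        ref = find_fixed_differences(aln, meta).positions
        # permute
        order = list(range(len(aln.seqs)))
        rng.shuffle(order)
        shuffled = Alignment("L", tuple(aln.seqs[i] for i in order))
        assert find_fixed_differences(shuffled, meta).positions == ref
        # duplicate a parental sample
        dup = Alignment(
            "L", aln.seqs + (AlignedSeq("a_dup", "L", a[0]),)
        )
        meta_dup = meta + [SampleMeta("a_dup", PARENTAL_A)]
        assert find_fixed_differences(dup, meta_dup).positions == ref

    def test_single_discordant_parental_removes_site(self):
        aln, meta = _dataset(["AAAA", "AAAA"], ["AAAT", "AAAT"])
        assert find_fixed_differences(aln, meta).positions == (4,)
        discordant = Alignment("L", aln.seqs + (AlignedSeq("b9", "L", "AAAA"),))
        meta9 = meta + [SampleMeta("b9", PARENTAL_B)]
        assert find_fixed_differences(discordant, meta9).positions == ()

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_matches_bruteforce_oracle(self, data):
        length = data.draw(st.integers(2, 25))
        seq = st.text(alphabet="ACGTRN-", min_size=length, max_size=length)
        a = data.draw(st.lists(seq, min_size=1, max_size=5))
        b = data.draw(st.lists(seq, min_size=1, max_size=5))
        aln, meta = _dataset(a, b)
        assert list(find_fixed_differences(aln, meta).positions) == _bruteforce_fixed(a, b)


class TestDetectHetSites:
    def test_simple_r(self):
        hits = detect_het_sites(AlignedSeq("s", "L", "ACRT"))
        assert [(h.position, h.symbol, set(h.expansion)) for h in hits] == [
            (3, "R", {"A", "G"})
        ]

    def test_plain_sequence_empty(self):
        assert detect_het_sites(AlignedSeq("s", "L", "ACGTACGT")) == []

    def test_n_excluded_by_default(self):
        seq = AlignedSeq("s", "L", "ANYT")
        assert [h.position for h in detect_het_sites(seq)] == [3]
        assert [h.position for h in detect_het_sites(seq, include_n=True)] == [2, 3]

    def test_three_base_codes_detected(self):
        hits = detect_het_sites(AlignedSeq("s", "L", "ABGT"))
        assert [(h.position, h.symbol) for h in hits] == [(2, "B")]

    def test_hybrid_consensus_sites_match_generator_truth(self, full_fixture):
        alignments, _, _ = full_fixture
        hits = detect_het_sites(alignments["Wg"].get("CFR01"))
        assert [h.position for h in hits] == [213, 271]


SITES = DiagnosticSiteSet(
    locus="L",
    sites=(DiagnosticSite(2, "A", "G"), DiagnosticSite(4, "C", "T")),
)


class TestZygosityProfile:
    def test_parental_b_all_hom_b(self):
        prof = zygosity_profile(AlignedSeq("s", "L", "TGTT"), SITES)
        assert prof.calls == {2: HOM_B, 4: HOM_B}
        assert prof.n_hom_b == 2

    def test_heterozygote(self):
        prof = zygosity_profile(AlignedSeq("s", "L", "TRTY"), SITES)
        assert prof.calls == {2: HET_AB, 4: HET_AB}

    def test_n_is_other(self):
        prof = zygosity_profile(AlignedSeq("s", "L", "TNTC"), SITES)
        assert prof.calls[2] == OTHER
        assert prof.calls[4] == HOM_A

    def test_wrong_ambiguity_code_is_other(self):
        # W = {A,T} does not equal {A,G} at site 2
        prof = zygosity_profile(AlignedSeq("s", "L", "TWTC"), SITES)
        assert prof.calls[2] == OTHER

    def test_sequence_too_short(self):
        with pytest.raises(ConfigurationError):
            zygosity_profile(AlignedSeq("s", "L", "TG"), SITES)

    def test_fixture_hybrids_het_at_all_nuclear_sites(self, full_fixture):
        alignments, meta, _ = full_fixture
        for locus in ("Wg", "CaATP"):
            ds = find_fixed_differences(alignments[locus], meta)
            for q in ("CFR01", "CFR02", "CFR03"):
                prof = zygosity_profile(alignments[locus].get(q), ds)
                assert prof.n_het_ab == 2 and prof.n_sites == 2


class TestPDistance:
    def test_reference_haplotypes_ah01_cl01(self):
        haps = coi_haplotype_sequences()
        assert p_distance(haps["Ah01"], haps["Cl01"]) == pytest.approx(4 / 658)

    def test_reference_haplotypes_ah01_cl03(self):
        haps = coi_haplotype_sequences()
        assert p_distance(haps["Ah01"], haps["Cl03"]) == pytest.approx(7 / 658)

    def test_identical_zero(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_pairwise_deletion(self):
        # one gap and one ambiguity leave 2 comparable sites, 1 differing
        assert p_distance("A-RT", "ACGA") == pytest.approx(1 / 2)

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NN--", "ACGT")

    def test_length_mismatch(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("ACG", "ACGT")


def _bruteforce_mean(aln, pairs):
    vals = [p_distance(aln.seqs[i], aln.seqs[j]) for i, j in pairs]
    return sum(vals) / len(vals)


class TestMeanPDistance:
    def test_fixture_overall_matches_weighted_oracle(self, coi_aln, coi_meta):
        res = mean_p_distance(coi_aln, OVERALL, coi_meta, bootstrap_reps=0)
        # oracle: pair-weighted mean of haplotype Hamming distances,
        # multiplicities 12/14/1/2/1, all 658 sites comparable
        assert res.mean_p == pytest.approx((1090 / 435) / 658)
        assert round(100 * res.mean_p, 1) == 0.4
        assert res.n_pairs == 435

    def test_two_identical_sequences(self):
        aln = Alignment("L", (AlignedSeq("x", "L", "ACGT"), AlignedSeq("y", "L", "ACGT")))
        res = mean_p_distance(aln, OVERALL, bootstrap_reps=100, seed=1)
        assert res.mean_p == 0.0
        assert res.se_p == 0.0

    def test_pair_consistency(self):
        aln = Alignment("L", (AlignedSeq("x", "L", "ACGTAC"), AlignedSeq("y", "L", "ACGTTT")))
        res = mean_p_distance(aln, OVERALL, bootstrap_reps=0)
        assert res.mean_p == pytest.approx(p_distance("ACGTAC", "ACGTTT"))

    def test_matches_bruteforce_double_loop(self):
        rng = random.Random(11)
        for _ in range(10):
            n = rng.randint(2, 12)
            length = rng.randint(5, 60)
            seqs = tuple(
                AlignedSeq(
                    f"s{i}", "L",
                    "".join(rng.choice("ACGTN-") for _ in range(length)),
                )
                for i in range(n)
            )
            aln = Alignment("L", seqs)
            pairs = list(itertools.combinations(range(n), 2))
            try:
                expected = _bruteforce_mean(aln, pairs)
            except UndefinedDistanceError:
                with pytest.raises(UndefinedDistanceError):
                    mean_p_distance(aln, OVERALL, bootstrap_reps=0)
                continue
            res = mean_p_distance(aln, OVERALL, bootstrap_reps=0)
            assert res.mean_p == pytest.approx(expected)

    def test_between_groups_oracle(self, coi_aln, coi_meta):
        res = mean_p_distance(coi_aln, BETWEEN_GROUPS, coi_meta, bootstrap_reps=0)
        ids = {m.sample_id: m.group for m in coi_meta}
        vals = [
            p_distance(x, y)
            for x in coi_aln
            for y in coi_aln
            if ids[x.sample_id] == PARENTAL_A and ids[y.sample_id] == PARENTAL_B
        ]
        assert res.mean_p == pytest.approx(sum(vals) / len(vals))
        assert res.n_pairs == 12 * 15

    def test_bootstrap_reproducible(self, coi_aln, coi_meta):
        r1 = mean_p_distance(coi_aln, OVERALL, coi_meta, bootstrap_reps=200, seed=9)
        r2 = mean_p_distance(coi_aln, OVERALL, coi_meta, bootstrap_reps=200, seed=9)
        assert r1.se_p == r2.se_p

    def test_bootstrap_requires_seed(self, coi_aln, coi_meta):
        with pytest.raises(ConfigurationError):
            mean_p_distance(coi_aln, OVERALL, coi_meta, bootstrap_reps=10, seed=None)

    def test_fixture_se_rounds_to_reported_value(self, coi_aln, coi_meta):
        res = mean_p_distance(coi_aln, OVERALL, coi_meta, bootstrap_reps=1000, seed=1)
        assert round(100 * res.se_p, 1) == 0.2

    def test_unknown_mode(self, coi_aln):
        with pytest.raises(ConfigurationError):
            mean_p_distance(coi_aln, "sideways", bootstrap_reps=0)
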