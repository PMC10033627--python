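import numpy as np
import pytest

from unihaced.core_io import IUPAC_CODES, MitoRecord, NucSeq, expand_degenerate, revcomp
from unihaced.errors import ContractError
from unihaced.primer_design import (
    amplicon_length_stats,
    consensus_sequence,
    design_primer,
    gap_identity_score,
    in_silico_pcr,
    profile_alignment,
)


def _column_msa(columns, n_rows):
    """Build an alignment whose j-th column is columns[j] (a string of
    length n_rows over ACGT-)."""
    return ["".join(col[i] for col in columns) for i in range(n_rows)]


class TestProfileAlignment:
    def test_identical_rows(self):
        profiles = profile_alignment(["ACGT"] * 10)
        assert all(p.occupancy == 1.0 for p in profiles)
        assert all(p.consensus_fraction == 1.0 for p in profiles)
        assert [p.consensus_base for p in profiles] == list("ACGT")

    def test_gap_column(self):
        msa = _column_msa(["A" * 9 + "-"], 10)
        p = profile_alignment(msa)[0]
        assert p.occupancy == pytest.approx(0.9)
        assert p.consensus_base == "A"
        assert p.consensus_fraction == 1.0

    def test_mixed_column(self):
        msa = _column_msa(["A" * 6 + "G" * 3 + "-"], 10)
        p = profile_alignment(msa)[0]
        assert p.occupancy == pytest.approx(0.9)
        assert p.consensus_base == "A"
        assert p.consensus_fraction == pytest.approx(6 / 9)

    def test_ragged_rows_rejected(self):
        with pytest.raises(ContractError):
            profile_alignment(["ACGT", "ACG"])


class TestConsensusSequence:
    def test_full_occupancy_keeps_all(self):
        profiles = profile_alignment(["ACGTACGT"] * 5)
        seq, idx = consensus_sequence(profiles)
        assert seq == "ACGTACGT"
        assert idx == list(range(8))

    def test_alternating_occupancy(self):
        # odd columns half-gapped -> dropped by the >90% occupancy rule
        cols = []
        for j in range(8):
            cols.append("A" * 10 if j % 2 == 0 else "C" * 5 + "-" * 5)
        profiles = profile_alignment(_column_msa(cols, 10))
        seq, idx = consensus_sequence(profiles)
        assert seq == "AAAA"
        assert idx == [0, 2, 4, 6]

    def test_planted_085_occupancy_block_excluded(self):
        # 20 rows; a 5-column block where exactly 17/20 rows are aligned
        n = 20
        cols = ["A" * n] * 4 + ["G" * 17 + "-" * 3] * 5 + ["T" * n] * 4
        profiles = profile_alignment(_column_msa(cols, n))
        seq, idx = consensus_sequence(profiles)
        assert seq == "AAAATTTT"
        assert idx == [0, 1, 2, 3, 9, 10, 11, 12]

    def test_length_equals_high_occupancy_column_count(self):
        rng = np.random.default_rng(0)
        n = 10
        cols = []
        for _ in range(50):
            gaps = int(rng.integers(0, 5))
            cols.append("A" * (n - gaps) + "-" * gaps)
        profiles = profile_alignment(_column_msa(cols, n))
        seq, _ = consensus_sequence(profiles, occupancy_threshold=0.90)
        expected = sum(1 for p in profiles if p.occupancy > 0.90)
        assert len(seq) == expected


class TestGapIdentityScore:
    def test_pure_accumulation(self):
        profiles = profile_alignment(["A" * 10] * 4)
        track = gap_identity_score(profiles)
        assert track.tolist() == pytest.approx(list(range(1, 11)))

    def test_subtraction_after_gap_region(self):
        cols = ["A" * 10] * 5 + ["A" * 5 + "-" * 5] * 5
        profiles = profile_alignment(_column_msa(cols, 10))
        track = gap_identity_score(profiles)
        assert track.tolist() == pytest.approx([1, 2, 3, 4, 5, 4, 3, 2, 1, 0])

    def test_hand_traced_mixed_track(self):
        # fractions {1, 1, 0.9, low-occupancy, 1} -> {1, 2, 2.9, 1.9, 2.9}
        n = 10
        cols = ["A" * n, "C" * n, "G" * 9 + "T", "A" * 5 + "-" * 5, "T" * n]
        profiles = profile_alignment(_column_msa(cols, n))
        track = gap_identity_score(profiles)
        assert track.tolist() == pytest.approx([1.0, 2.0, 2.9, 1.9, 2.9])

    def test_never_negative_and_bounded(self):
        rng = np.random.default_rng(3)
        n = 12
        cols = []
        for _ in range(80):
            gaps = int(rng.integers(0, 6))
            bases = "".join(rng.choice(list("ACGT"), size=n - gaps))
            cols.append(bases + "-" * gaps)
        profiles = profile_alignment(_column_msa(cols, n))
        track = gap_identity_score(profiles)
        assert (track >= 0).all()
        high = np.cumsum([p.occupancy > 0.90 for p in profiles])
        assert (track <= high + 1e-9).all()


class TestDesignPrimer:
    def test_conserved_column_emits_consensus(self):
        cols = ["A" * 18 + "G" * 2]  # 90% A
        profiles = profile_alignment(_column_msa(cols, 20))
        primer = design_primer(profiles, (0, 1))
        assert primer.seq == "A"

    def test_mixed_column_emits_minimal_covering_code(self):
        # A:0.60 G:0.38 T:0.02 -> A+G covers 98% >= 95% -> R
        cols = ["A" * 30 + "G" * 19 + "T"]
        profiles = profile_alignment(_column_msa(cols, 50))
        primer = design_primer(profiles, (0, 1))
        assert primer.seq == "R"

    def test_window_in_low_occupancy_region_rejected(self):
        cols = ["A" * 5 + "-" * 5]
        profiles = profile_alignment(_column_msa(cols, 10))
        with pytest.raises(ContractError):
            design_primer(profiles, (0, 1))

    def test_expansions_only_use_observed_bases(self):
        rng = np.random.default_rng(7)
        n = 40
        cols = []
        for _ in range(12):
            counts = rng.multinomial(n, [0.55, 0.35, 0.07, 0.03])
            cols.append("".join(b * c for b, c in zip("ACGT", counts)))
        profiles = profile_alignment(_column_msa(cols, n))
        primer = design_primer(profiles, (0, 12))
        for exp in expand_degenerate(primer.seq):
            for j, base in enumerate(exp):
                assert profiles[j].base_counts[base] > 0

    def test_published_reverse_primer_has_two_degenerate_sites(self):
        primer = "CGGAKACTTGCATGTRTAA"
        degenerate = [c for c in primer if len(IUPAC_CODES[c]) > 1]
        assert degenerate == ["K", "R"]


def _record(accession, seq):
    return MitoRecord(accession=accession, species=accession,
                      seq=NucSeq(id=accession, seq=seq))


class TestInSilicoPcr:
    FWD = "ARAGCRYCGGTCTTGTAA"
    REV = "CGGAKACTTGCATGTRTAA"

    def _planted(self, rng, n_mismatch_f=0, n_mismatch_r=0, insert_len=1200):
        fwd_site = expand_degenerate(self.FWD)[0]
        rev_site = expand_degenerate(self.REV)[0]

        def mutate(s, k):
            s = list(s)
            for p in rng.choice(len(s), size=k, replace=False):
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s)

        left = "".join(rng.choice(list("ACGT"), size=100))
        right = "".join(rng.choice(list("ACGT"), size=100))
        insert = "".join(rng.choice(list("ACGT"), size=insert_len))
        seq = (left + mutate(fwd_site, n_mismatch_f) + insert
               + revcomp(mutate(rev_site, n_mismatch_r)) + right)
        return seq

    def test_exact_planted_sites_hit_with_expected_length(self, rng):
        rec = _record("P1", self._planted(rng, insert_len=1200))
        df = in_silico_pcr(self.FWD, self.REV, [rec])
        assert bool(df.loc[0, "hit"])
        assert df.loc[0, "amplicon_length"] == 1200
        assert df.loc[0, "mismatches"] == 0

    def test_fwd_site_only_is_no_hit(self, rng):
        fwd_site = expand_degenerate(self.FWD)[0]
        seq = "".join(rng.choice(list("ACGT"), size=800))
        rec = _record("F1", seq[:100] + fwd_site + seq[100:])
        df = in_silico_pcr(self.FWD, self.REV, [rec])
        assert not bool(df.loc[0, "hit"])

    def test_reverse_strand_hit(self, rng):
        rec = _record("R1", revcomp(self._planted(rng, insert_len=900)))
        df = in_silico_pcr(self.FWD, self.REV, [rec])
        assert bool(df.loc[0, "hit"])
        assert df.loc[0, "amplicon_length"] == 900

    def test_hit_rate_on_planted_database(self, rng):
        db = []
        for i in range(45):
            db.append(_record(f"OK{i}", self._planted(
                rng, n_mismatch_f=int(rng.integers(0, 3)),
                n_mismatch_r=int(rng.integers(0, 3)),
                insert_len=int(rng.integers(800, 1500)))))
        for i in range(5):
            db.append(_record(f"BAD{i}",
                              "".join(rng.choice(list("ACGT"), size=1500))))
        df = in_silico_pcr(self.FWD, self.REV, db)
        assert df["hit"].mean() == pytest.approx(0.90)
        assert df.loc[df["accession"].str.startswith("OK"), "hit"].all()

    def test_agrees_with_brute_force_scan(self, rng):
        # exhaustive oracle: every expansion x every position x both strands
        def brute_force_hit(seq, max_mm=2, lo=500, hi=3000):
            for strand_seq in (seq, revcomp(seq)):
                f_hits, r_hits = [], []
                for exp in expand_degenerate(self.FWD):
                    for p in range(len(strand_seq) - len(exp) + 1):
                        w = strand_seq[p:p + len(exp)]
                        if sum(a != b for a, b in zip(w, exp)) <= max_mm:
                            f_hits.append(p + len(exp))
                for exp in expand_degenerate(self.REV):
                    rc = revcomp(exp)
                    for p in range(len(strand_seq) - len(rc) + 1):
                        w = strand_seq[p:p + len(rc)]
                        if sum(a != b for a, b in zip(w, rc)) <= max_mm:
                            r_hits.append(p)
                for f in f_hits:
                    for r in r_hits:
                        if lo <= r - f <= hi:
                            return True
            return False

        db = []
        for i in range(6):
            if i % 2 == 0:
                db.append(_record(f"S{i}", self._planted(
                    rng, n_mismatch_f=int(rng.integers(0, 4)),
                    insert_len=600)))
            else:
                db.append(_record(
                    f"S{i}", "".join(rng.choice(list("ACGT"), size=900))))
        df = in_silico_pcr(self.FWD, self.REV, db)
        for _, row in df.iterrows():
            rec = next(r for r in db if r.accession == row["accession"])
            assert bool(row["hit"]) == brute_force_hit(rec.seq.seq)

    def test_inverted_range_rejected(self, rng):
        rec = _record("X", self._planted(rng))
        with pytest.raises(ContractError):
            in_silico_pcr(self.FWD, self.REV, [rec], amplicon_range=(3000, 500))


class TestAmpliconLengthStats:
    def test_constant(self):
        s = amplicon_length_stats([1000, 1000, 1000])
        assert s == {"mean": 1000.0, "q25": 1000.0, "q75": 1000.0}

    def test_small_sample_mean(self):
        assert amplicon_length_stats([1, 2, 3, 4])["mean"] == 2.5

    def test_normal_sample_mean(self):
        rng = np.random.default_rng(42)
        lengths = rng.normal(1200, 50, size=1000)
        s = amplicon_length_stats(lengths)
        assert abs(s["mean"] - 1200) < 5
        assert s["q25"] < s["mean"] < s["q75"]

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            amplicon_length_stats([])
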