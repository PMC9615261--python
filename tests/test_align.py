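"""Internal aligner: examples, strand symmetry, and an exhaustive-scan oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tepirna.align import map_reads, substitution_profile
from tepirna.records import AlignmentHit, SequenceRecord, TERecord, revcomp


def _exhaustive_smallrna(read, library, max_mismatch):
    """Definition-based oracle: scan every substring on both strands."""
    out = set()
    best = max_mismatch + 1
    L = len(read.seq)
    for strand in "+-":
        oriented = read.seq if strand == "+" else revcomp(read.seq)
        for rec in library:
            for start in range(len(rec.seq) - L + 1):
                window = rec.seq[start : start + L]
                mm = sum(
                    1
                    for a, b in zip(oriented, window)
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mismatch:
                    if mm < best:
                        best = mm
                        out = set()
                    if mm == best:
                        out.add((rec.id, strand, start, mm))
    return out


def _hitset(hits):
    return {(h.target_id, h.strand, h.t_start, h.mismatches) for h in hits}


class TestSmallRNAMode:
    def test_exact_substring_single_hit(self, tiny_library):
        te = tiny_library[0]
        read = SequenceRecord("r", te.seq[100:125])
        (hit,) = map_reads([read], tiny_library, "smallrna")
        assert (hit.target_id, hit.strand, hit.t_start, hit.mismatches) == (
            te.id, "+", 100, 0,
        )
        assert hit.weight == 1.0

    def test_reverse_complement_flips_strand(self, tiny_library):
        te = tiny_library[0]
        read = SequenceRecord("r", revcomp(te.seq[100:125]))
        (hit,) = map_reads([read], tiny_library, "smallrna")
        assert (hit.target_id, hit.strand, hit.t_start) == (te.id, "-", 100)

    def test_too_many_mismatches_yields_no_hit(self, tiny_library, rng):
        te = tiny_library[0]
        frag = list(te.seq[100:125])
        for pos in (2, 8, 14, 20):  # 4 substitutions, budget is 3
            frag[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[pos]]
        read = SequenceRecord("r", "".join(frag))
        hits = map_reads([read], tiny_library, "smallrna", max_mismatch=3)
        assert _hitset(hits) == _exhaustive_smallrna(read, tiny_library, 3)

    def test_best_stratum_only(self, tiny_library):
        # plant the same 25-mer exactly in TE_A and with 1 mismatch in TE_B
        frag = tiny_library[0].seq[10:35]
        mutated = ("C" if frag[12] != "C" else "G") + frag[1:]
        lib = [
            tiny_library[0],
            TERecord("TE_B2", "LINE", None, tiny_library[1].seq + mutated + tiny_library[1].seq),
        ]
        read = SequenceRecord("r", frag)
        hits = map_reads([read], lib, "smallrna", max_mismatch=3)
        assert {h.target_id for h in hits} == {"TE_A"}  # 0-mm stratum wins

    def test_multimap_weights_sum_to_one(self, tiny_library):
        frag = tiny_library[0].seq[50:75]
        lib = list(tiny_library) + [
            TERecord("TE_D", "LTR", None, tiny_library[2].seq + frag)
        ]
        read = SequenceRecord("r", frag)
        hits = map_reads([read], lib, "smallrna")
        assert {h.target_id for h in hits} == {"TE_A", "TE_D"}
        assert sum(h.weight for h in hits) == pytest.approx(1.0)
        assert all(h.weight == pytest.approx(0.5) for h in hits)

    def test_read_longer_than_50_rejected(self, tiny_library):
        read = SequenceRecord("r", "A" * 60)
        with pytest.raises(ValueError, match="50"):
            map_reads([read], tiny_library, "smallrna")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_oracle_equivalence(self, tiny_library, data):
        """smallrna mode equals the exhaustive scan on random reads."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        mm = data.draw(st.integers(0, 3))
        if rng.random() < 0.5:  # read derived from a library sequence
            te = tiny_library[int(rng.integers(len(tiny_library)))]
            L = int(rng.integers(20, 36))
            start = int(rng.integers(0, len(te.seq) - L + 1))
            seq = list(te.seq[start : start + L])
            for pos in rng.choice(L, size=int(rng.integers(0, 5)), replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.5:
                seq = list(revcomp("".join(seq)))
            read = SequenceRecord("r", "".join(seq))
        else:  # random read
            read = SequenceRecord("r", "".join("ACGT"[i] for i in rng.integers(0, 4, 28)))
        hits = map_reads([read], tiny_library, "smallrna", max_mismatch=mm)
        assert _hitset(hits) == _exhaustive_smallrna(read, tiny_library, mm)


class TestGenomicMode:
    def test_planted_fragment_recovered_both_strands(self, tiny_library):
        te = tiny_library[0]
        fwd = SequenceRecord("f", te.seq[37:187])
        rev = SequenceRecord("r", revcomp(te.seq[37:187]))
        hits = map_reads([fwd, rev], tiny_library, "genomic")
        by_id = {h.query_id: h for h in hits}
        assert (by_id["f"].strand, by_id["f"].t_start, by_id["f"].t_end) == ("+", 37, 187)
        assert (by_id["r"].strand, by_id["r"].t_start, by_id["r"].t_end) == ("-", 37, 187)
        assert by_id["f"].matches == 150

    def test_single_best_hit_per_read(self, tiny_library):
        te = tiny_library[0]
        # fragment present in TE_A and duplicated into a new target: tie on
        # score resolved by lexicographically smallest target id
        frag = te.seq[0:120]
        lib = list(tiny_library) + [TERecord("AAA_first", "LTR", None, frag)]
        hits = map_reads([SequenceRecord("q", frag)], lib, "genomic")
        assert len(hits) == 1
        assert hits[0].target_id == "AAA_first"

    def test_background_read_gives_no_hit(self, tiny_library, rng):
        read = SequenceRecord("bg", "".join("ACGT"[i] for i in rng.integers(0, 4, 150)))
        assert map_reads([read], tiny_library, "genomic") == []

    def test_seed_longer_than_read_rejected(self, tiny_library):
        read = SequenceRecord("r", "ACGTACGTAC")
        with pytest.raises(ValueError, match="seed_k"):
            map_reads([read], tiny_library, "genomic", seed_k=12)

    def test_divergent_copy_counts_substitutions(self, tiny_library):
        te = tiny_library[0]
        frag = list(te.seq[50:200])
        # one transition (A<->G or C<->T) and one transversion
        ts_pos, tv_pos = 40, 90
        frag[ts_pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[frag[ts_pos]]
        frag[tv_pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[tv_pos]]
        (hit,) = map_reads([SequenceRecord("q", "".join(frag))], tiny_library, "genomic")
        assert (hit.transitions, hit.transversions) == (1, 1)
        assert hit.aligned_len == hit.matches + 2


class TestSubstitutionProfile:
    def _hit(self, qlen):
        return AlignmentHit("q", "t", "+", 0, qlen, 0, qlen, qlen, qlen, 0, 0)

    def test_transition_fraction(self):
        target = TERecord("t", "LTR", None, "GCGT" + "A" * 46)
        query = SequenceRecord("q", "ACGT" + "A" * 46)
        hit = AlignmentHit("q", "t", "+", 0, 4, 0, 4, 4, 3, 1, 0)
        P, Q = substitution_profile(hit, query, target)
        assert (P, Q) == (0.25, 0.0)  # A<->G is a transition

    def test_transversion_fraction(self):
        target = TERecord("t", "LTR", None, "CCGT" + "A" * 46)
        query = SequenceRecord("q", "ACGT" + "A" * 46)
        hit = AlignmentHit("q", "t", "+", 0, 4, 0, 4, 4, 3, 0, 1)
        P, Q = substitution_profile(hit, query, target)
        assert (P, Q) == (0.0, 0.25)  # A<->C is a transversion

    def test_identical_sequences(self):
        seq = "ACGT" * 25
        target = TERecord("t", "LTR", None, seq)
        hit = self._hit(100)
        assert substitution_profile(hit, SequenceRecord("q", seq), target) == (0.0, 0.0)

    def test_n_columns_excluded(self):
        target = TERecord("t", "LTR", None, "A" * 50)
        query = SequenceRecord("q", "N" + "A" * 24 + "G" + "A" * 25)
        hit = AlignmentHit("q", "t", "+", 0, 50, 0, 50, 49, 48, 1, 0)
        P, Q = substitution_profile(hit, query, target)
        assert P == pytest.approx(1 / 49)

    def test_inconsistent_coordinates_rejected(self):
        target = TERecord("t", "LTR", None, "A" * 50)
        query = SequenceRecord("q", "A" * 10)
        bad = AlignmentHit("q", "t", "+", 0, 10, 0, 12, 10, 10, 0, 0)
        with pytest.raises(ValueError, match="interval"):
            substitution_profile(bad, query, target)

    def test_p_plus_q_equals_mismatch_fraction(self, tiny_library, rng):
        """P + Q must equal mismatches / aligned_len exactly for real hits."""
        te = tiny_library[0]
        frag = list(te.seq[30:180])
        for pos in rng.choice(len(frag), size=12, replace=False):
            frag[pos] = "ACGT"[int(rng.integers(4))]
        read = SequenceRecord("q", "".join(frag))
        (hit,) = map_reads([read], tiny_library, "genomic")
        P, Q = substitution_profile(hit, read, te)
        assert P + Q == pytest.approx(hit.mismatches / hit.aligned_len, abs=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_strand_symmetry(tiny_library, seed):
    """Mapping a read and its reverse complement flips strands only."""
    rng = np.random.default_rng(seed)
    te = tiny_library[int(rng.integers(len(tiny_library)))]
    L = int(rng.integers(23, 41))
    start = int(rng.integers(0, len(te.seq) - L + 1))
    read = SequenceRecord("r", te.seq[start : start + L])
    flipped = SequenceRecord("r", revcomp(read.seq))
    fwd = _hitset(map_reads([read], tiny_library, "smallrna"))
    rev = _hitset(map_reads([flipped], tiny_library, "smallrna"))
    swap = {"+": "-", "-": "+"}
    assert {(t, swap[s], p, m) for t, s, p, m in fwd} == rev
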