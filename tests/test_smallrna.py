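"""Small-RNA pipeline: trimming, classification order, piRNA rules, RPM."""

import numpy as np
import pandas as pd
import pytest

from tepirna.records import SequenceRecord, TERecord, revcomp
from tepirna.simulate import (
    FamilySpec,
    SmallRNASpec,
    random_references,
    simulate_small_rna,
    simulate_te_library,
)
from tepirna.smallrna import (
    PirnaRecord,
    base_bias,
    identify_mirna,
    identify_te_pirna,
    pirna_abundance,
    preprocess_small_rna,
    remove_contaminants,
    rpm_normalize,
    run_small_rna_pipeline,
)

ADAPTER = "AGATCGGAAGAGCACACGTCTGAAC"


def _seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPreprocess:
    def test_full_adapter_trimmed(self, rng):
        insert = _seq(rng, 24)
        read = SequenceRecord("r", insert + ADAPTER)
        res = preprocess_small_rna([read], ADAPTER)
        assert [r.seq for r in res.retained] == [insert]
        assert res.length_hist[24] == 1

    def test_partial_adapter_suffix_trimmed(self, rng):
        insert = _seq(rng, 26)
        read = SequenceRecord("r", insert + ADAPTER[:6])  # only 6 nt of adapter
        res = preprocess_small_rna([read], ADAPTER)
        assert [r.seq for r in res.retained] == [insert]

    def test_short_insert_discarded(self, rng):
        read = SequenceRecord("r", _seq(rng, 17) + ADAPTER)
        res = preprocess_small_rna([read], ADAPTER)
        assert res.retained == [] and res.n_too_short == 1

    def test_overlong_read_discarded(self, rng):
        res = preprocess_small_rna([SequenceRecord("r", _seq(rng, 40))], adapter=None)
        assert res.retained == [] and res.n_too_long == 1

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError, match="10 nt"):
            preprocess_small_rna([], adapter="ACGT")

    def test_length_histogram_matches_truth_on_adapterless_reads(self):
        specs = [FamilySpec("f0", "LTR", consensus_len=300, copy_number=0)]
        lib = simulate_te_library(specs, 0)
        sim = simulate_small_rna(
            SmallRNASpec(n_reads=2000, pirna_fraction=1.0, mirna_fraction=0.0,
                         contaminant_fraction=0.0),
            lib, [], [], seed=0,
        )
        res = preprocess_small_rna(sim.reads)
        truth_hist = sim.truth["length"].value_counts().sort_index()
        assert res.length_hist.to_dict() == truth_hist.to_dict()


class TestContaminantsAndMirna:
    def test_contaminant_substring_removed(self, rng):
        ref = SequenceRecord("rrna", _seq(rng, 400))
        read = SequenceRecord("r", ref.seq[100:125])
        kept, frac = remove_contaminants([read], [ref])
        assert kept == [] and frac == 1.0

    def test_distant_read_kept(self, rng):
        ref = SequenceRecord("rrna", _seq(rng, 400))
        read = SequenceRecord("r", _seq(rng, 25))
        kept, frac = remove_contaminants([read], [ref])
        assert [r.id for r in kept] == ["r"] and frac == 0.0

    def test_no_refs_is_noop_with_warning(self, rng):
        read = SequenceRecord("r", _seq(rng, 25))
        with pytest.warns(UserWarning, match="skipping"):
            kept, frac = remove_contaminants([read], [])
        assert kept == [read] and frac == 0.0

    def test_hairpin_arm_is_mirna(self, rng):
        hp = SequenceRecord("mir1", _seq(rng, 80))
        read = SequenceRecord("r", hp.seq[:22])
        mirna, rest, frac = identify_mirna([read], [hp])
        assert [r.id for r in mirna] == ["r"] and rest == [] and frac == 1.0

    def test_random_22mer_is_not_mirna(self, rng):
        hp = SequenceRecord("mir1", _seq(rng, 80))
        read = SequenceRecord("r", _seq(rng, 22))
        mirna, rest, _ = identify_mirna([read], [hp])
        assert mirna == [] and [r.id for r in rest] == ["r"]


class TestPirnaIdentification:
    def test_sense_and_antisense_orientation(self, tiny_library):
        te = tiny_library[0]
        sense = SequenceRecord("s", te.seq[10:35])
        anti = SequenceRecord("a", revcomp(te.seq[40:65]))
        recs = identify_te_pirna([sense, anti], tiny_library)
        by_id = {r.read_id: r for r in recs}
        assert by_id["s"].orientation == "sense" and by_id["s"].weight == 1.0
        assert by_id["a"].orientation == "antisense"

    def test_22mer_perfect_match_is_not_pirna(self, tiny_library):
        te = tiny_library[0]
        read = SequenceRecord("r", te.seq[10:32])  # 22 nt: below the piRNA range
        assert identify_te_pirna([read], tiny_library) == []

    def test_multimap_read_split_across_families(self, tiny_library):
        frag = tiny_library[0].seq[60:85]
        lib = list(tiny_library) + [TERecord("TE_D", "LTR", None,
                                             tiny_library[2].seq + frag)]
        recs = identify_te_pirna([SequenceRecord("r", frag)], lib)
        assert {r.family_id for r in recs} == {"TE_A", "TE_D"}
        assert all(r.weight == pytest.approx(0.5) for r in recs)

    def test_transcripts_collapse_onto_family(self, tiny_library):
        te = tiny_library[0]
        tx = SequenceRecord("TE_A_tx", te.seq[5:200])
        frag = te.seq[20:45]
        recs = identify_te_pirna(
            [SequenceRecord("r", frag)],
            list(tiny_library) + [tx],
            target_to_family={"TE_A_tx": "TE_A"},
        )
        (rec,) = recs  # consensus + transcript hits deduplicate to one family
        assert rec.family_id == "TE_A" and rec.weight == 1.0

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            identify_te_pirna([], [])


class TestBaseBiasAndRPM:
    def test_u1_from_mixed_first_bases(self):
        reads = [
            SequenceRecord("a", "TAAG" + "A" * 21),
            SequenceRecord("b", "GAAA" + "A" * 21),
            SequenceRecord("c", "TTTT" + "A" * 21),
            SequenceRecord("d", "CCCC" + "A" * 21),
        ]
        pirnas = [PirnaRecord(r.id, "F", "sense", 1.0, r.seq[0]) for r in reads]
        bias, u1 = base_bias(pirnas, reads)
        assert u1 == pytest.approx(0.5)
        assert bias.loc[1].sum() == pytest.approx(1.0)

    def test_all_t_first_base(self):
        reads = [SequenceRecord(f"r{i}", "T" + "ACG"[i % 3] * 24) for i in range(6)]
        pirnas = [PirnaRecord(r.id, "F", "sense", 1.0, "T") for r in reads]
        _, u1 = base_bias(pirnas, reads)
        assert u1 == 1.0

    def test_empty_pirna_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            base_bias([], [])

    def test_rpm_arithmetic(self):
        out = rpm_normalize(pd.Series({"F": 1500.0}), denominator=50_000)
        assert out["F"] == pytest.approx(30_000.0)
        with pytest.raises(ValueError, match="denominator"):
            rpm_normalize(pd.Series({"F": 1.0}), 0)

    def test_zero_family_keeps_row(self):
        pirnas = [PirnaRecord("r", "F1", "sense", 1.0, "T")]
        ab = pirna_abundance(pirnas, 1000, families=["F1", "F2"])
        assert ab.loc["F2", "total_rpm"] == 0.0
        assert ab.loc["F1", "sense_rpm"] == pytest.approx(1000.0)

    def test_total_rpm_invariant_to_weight_split(self):
        """Conservation: the multi-map split never changes total piRNA RPM."""
        even = [
            PirnaRecord("r1", "A", "sense", 0.5, "T"),
            PirnaRecord("r1", "B", "sense", 0.5, "T"),
        ]
        skewed = [PirnaRecord("r1", "A", "sense", 1.0, "T")]
        t_even = pirna_abundance(even, 1000)["total_rpm"].sum()
        t_skew = pirna_abundance(skewed, 1000)["total_rpm"].sum()
        assert t_even == pytest.approx(t_skew)


class TestPipelineOrder:
    def test_te_matching_contaminant_is_contaminant(self, tiny_library):
        """A read matching both an rRNA reference and a TE stays a contaminant."""
        te = tiny_library[0]
        frag = te.seq[100:125]
        rrna = SequenceRecord("rrna", te.seq[80:160])  # shares the fragment
        res = run_small_rna_pipeline([SequenceRecord("r", frag)], tiny_library,
                                     contaminant_refs=[rrna])
        assert res.classes.loc[0, "class"] == "contaminant"
        assert res.pirnas == []

    def test_class_partition_sums_to_one(self, tiny_library, rng):
        specs = [FamilySpec(f"f{i}", "LTR", consensus_len=300, copy_number=0)
                 for i in range(3)]
        lib = simulate_te_library(specs, 5)
        cont = random_references("rrna", 2, 500, 6)
        hp = random_references("mir", 8, 70, 7)
        sim = simulate_small_rna(
            SmallRNASpec(n_reads=800, pirna_fraction=0.4, mirna_fraction=0.3,
                         contaminant_fraction=0.2),
            lib, cont, hp, seed=8,
        )
        res = run_small_rna_pipeline(sim.reads, lib, cont, hp)
        assert res.classes["class"].isin(
            ["contaminant", "miRNA", "piRNA", "unannotated"]
        ).all()
        assert sum(res.fractions.values()) == pytest.approx(1.0)

    def test_result_files_written(self, tiny_library, tmp_path, rng):
        frag = tiny_library[0].seq[100:125]
        res = run_small_rna_pipeline([SequenceRecord("r", frag)], tiny_library)
        res.write(tmp_path)
        import json
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["fractions"]["piRNA"] == 1.0
        assert (tmp_path / "pirna_abundance.tsv").exists()
        assert (tmp_path / "classes.tsv").exists()

    def test_precision_recall_on_simulated_pool(self, tiny_library):
        specs = [FamilySpec(f"f{i}", "LTR", consensus_len=400, copy_number=0)
                 for i in range(4)]
        lib = simulate_te_library(specs, 9)
        cont = random_references("rrna", 2, 600, 10)
        hp = random_references("mir", 10, 70, 11)
        sim = simulate_small_rna(
            SmallRNASpec(n_reads=3000, pirna_fraction=0.3, mirna_fraction=0.4,
                         contaminant_fraction=0.1),
            lib, cont, hp, seed=12,
        )
        res = run_small_rna_pipeline(sim.reads, lib, cont, hp)
        truth = sim.truth.set_index("read_id")["true_class"]
        called = res.classes.set_index("read_id")["class"]
        pirna_called = set(called[called == "piRNA"].index)
        pirna_true = set(truth[truth == "piRNA"].index)
        precision = len(pirna_called & pirna_true) / len(pirna_called)
        recall = len(pirna_called & pirna_true) / len(pirna_true)
        assert precision >= 0.99 and recall >= 0.99
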