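"""Read merging, demultiplexing, tabulation and misassignment filtering."""

from collections import Counter

import numpy as np
import pytest

from cleavedrive import seqio
from cleavedrive.seqio import (
    AmpliconScheme,
    ReadPair,
    Reference,
    classify_prefix,
    default_scheme,
    demultiplex,
    merge_pairs,
    misassignment_filter,
    reverse_complement,
    tabulate,
)

from conftest import random_seq


def make_pair(fwd, rev, q=40):
    return ReadPair("r", fwd, [q] * len(fwd), rev, [q] * len(rev))


class TestMergePairs:
    def test_full_length_identity(self, rng):
        frag = random_seq(rng, 40)
        pair = make_pair(frag, reverse_complement(frag))
        assert merge_pairs(pair) == frag

    def test_partial_overlap_reconstructs_fragment(self, rng):
        # fragment of 20; fwd covers 1-15, rev covers 6-20: overlap of 10
        frag = random_seq(rng, 20)
        pair = make_pair(frag[:15], reverse_complement(frag[5:]))
        assert merge_pairs(pair, min_overlap=10) == frag

    def test_no_overlap_returns_unmerged(self, rng):
        pair = make_pair("ACGT" * 10, "TTTT" * 10)
        assert merge_pairs(pair, min_overlap=10, max_mismatch_frac=0.0) is None

    def test_higher_quality_base_wins_at_mismatch(self, rng):
        frag = random_seq(rng, 30)
        rev = list(reverse_complement(frag))
        # plant a disagreement in the middle of the overlap
        pos = 15
        rc_pos = len(frag) - 1 - pos
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[rev[rc_pos]]
        rev[rc_pos] = wrong
        pair = ReadPair("r", frag, [40] * 30, "".join(rev), [2] * 30)
        assert merge_pairs(pair, max_mismatch_frac=0.1) == frag

    def test_swap_symmetry(self, rng):
        # swapping fwd/rev with reverse-complementation merges to the
        # reverse complement of the original merge
        frag = random_seq(rng, 25)
        fwd, rev = frag[:18], reverse_complement(frag[7:])
        a = merge_pairs(make_pair(fwd, rev), min_overlap=10)
        b = merge_pairs(make_pair(rev, fwd), min_overlap=10)
        assert a == frag
        assert b == reverse_complement(frag)

    def test_empty_read_rejected(self):
        with pytest.raises(seqio.MalformedReadError):
            ReadPair("r", "", [], "ACGT", [40] * 4)

    def test_parameter_validation(self, rng):
        pair = make_pair("ACGTACGTAC", "ACGTACGTAC")
        with pytest.raises(ValueError):
            merge_pairs(pair, min_overlap=3)
        with pytest.raises(ValueError):
            merge_pairs(pair, max_mismatch_frac=0.6)


class TestDemultiplex:
    def test_exact_match_strips_barcodes(self, scheme):
        b5, b3 = scheme.barcodes["minus"]
        body = "ACGT" * 10
        assert demultiplex(b5 + body + b3, scheme) == ("minus", body)

    def test_missing_barcode_unassigned(self, scheme):
        assert demultiplex("ACGT" * 10, scheme) is None

    def test_ambiguous_under_one_mismatch_is_unassigned(self):
        # two conditions whose barcodes differ at one position: a read
        # matching both within 1 mismatch must stay unassigned
        scheme = AmpliconScheme(
            prefixes={"W": "AAAC", "Z": "AAAG"},
            suffix="AAAT",
            barcodes={"c1": ("CAT", "CAT"), "c2": ("CGT", "GAT")},
        )
        read = "CTT" + "AAAC" + "ACGT" + "AAAT" + "CAT"
        # exhaustive check: read matches both c1 and c2 on the 5' side
        assert sum(
            read.startswith(bc[0]) or
            sum(a != b for a, b in zip(read[:3], bc[0])) <= 1
            for bc in scheme.barcodes.values()
        ) == 2
        qc = Counter()
        assert demultiplex(read, scheme, max_mismatch=1, qc=qc) is None
        assert qc["ambiguous"] == 1


class TestClassifyPrefix:
    @pytest.mark.parametrize("label", ["W", "Z", "A"])
    def test_each_prefix_recognized(self, scheme, label, rng):
        core = random_seq(rng, 50)
        body = scheme.prefixes[label] + core + scheme.suffix
        assert classify_prefix(body, scheme) == (label, core)

    def test_unrecognizable_body(self, scheme):
        assert classify_prefix("ACGT" * 5, scheme) == (None, "")

    def test_too_short_body(self, scheme):
        assert classify_prefix("ACG", scheme) == (None, "")

    def test_one_mismatch_tolerance(self, scheme, rng):
        core = random_seq(rng, 50)
        prefix = list(scheme.prefixes["W"])
        prefix[0] = "T"
        body = "".join(prefix) + core + scheme.suffix
        assert classify_prefix(body, scheme, max_mismatch=0) == (None, "")
        assert classify_prefix(body, scheme, max_mismatch=1) == ("W", core)


class TestTabulate:
    def test_counts_per_prefix(self, scheme):
        stream = [("ACGT", "Z", "minus", "1")] * 3 + [("ACGT", "W", "minus", "1")]
        table = tabulate(stream, scheme)
        assert table.counts("ACGT", "Z", "minus") == 3
        assert table.counts("ACGT", "W", "minus") == 1

    def test_reference_reads_routed_to_reference_rows(self, scheme):
        ref = scheme.references[0]
        table = tabulate([(ref.sequence, ref.prefix, "minus", "1")] * 5, scheme)
        assert table.samples.empty
        assert table.reference_reads(ref.prefix, "minus") == 5

    def test_order_invariance(self, scheme, rng):
        stream = [
            (random_seq(rng, 20), p, c, "1")
            for p in "WZ"
            for c in ("minus", "plus")
            for _ in range(5)
        ]
        t1 = tabulate(stream, scheme)
        shuffled = list(stream)
        rng.shuffle(shuffled)
        t2 = tabulate(shuffled, scheme)
        assert t1.data.equals(t2.data)

    def test_empty_stream(self, scheme):
        assert tabulate([], scheme).data.empty


class TestMisassignmentFilter:
    def make_table(self, scheme, counts):
        stream = [
            (core, "Z", "minus", "1") for core, n in counts.items() for _ in range(n)
        ]
        return tabulate(stream, scheme)

    def test_low_count_neighbor_of_abundant_core_flagged(self, scheme):
        table = self.make_table(scheme, {"ACGTACGT": 2000, "ACGTACGA": 10})
        assert misassignment_filter(table) == {"ACGTACGA"}
        assert table.data.loc[
            table.data["core_seq"] == "ACGTACGA", "flagged"
        ].all()

    def test_ratio_below_threshold_not_flagged(self, scheme):
        table = self.make_table(scheme, {"ACGTACGT": 400, "ACGTACGA": 10})
        assert misassignment_filter(table) == set()

    def test_distance_two_not_flagged_at_max_distance_one(self, scheme):
        table = self.make_table(scheme, {"ACGTACGT": 2000, "ACGTACAA": 10})
        assert misassignment_filter(table, max_distance=1) == set()


class TestSchemeValidation:
    def test_duplicate_prefixes_rejected(self):
        with pytest.raises(ValueError):
            AmpliconScheme({"W": "AAA", "Z": "AAA"}, "TTT", {"c": ("A", "C")})

    def test_non_prefix_free_barcodes_rejected(self):
        with pytest.raises(ValueError):
            AmpliconScheme(
                {"W": "AAA"}, "TTT", {"c1": ("CA", "G"), "c2": ("CAT", "T")}
            )

    def test_reference_concentration_positive(self):
        with pytest.raises(ValueError):
            Reference("ACGT", "W", 0.0)

    def test_yaml_round_trip(self, scheme, tmp_path):
        import yaml

        path = tmp_path / "scheme.yaml"
        path.write_text(yaml.safe_dump(scheme.to_dict()))
        loaded = AmpliconScheme.from_yaml(path)
        assert loaded == scheme


class TestFastqRoundTrip:
    def test_error_free_run_recovers_planted_counts(self, tmp_path):
        # full pipeline: synthetic FASTQ -> merge -> demux -> classify ->
        # tabulate must reproduce the generated count table exactly
        from cleavedrive.synthgen import TruthSpec, generate_cleaveseq_run

        truth = TruthSpec(
            members={
                "ACGTTGCAACGTTGCAACGTTGCAACGTTGCAACGTTGCAACGTTGCAAC": (0.7, 0.2),
                "TTGACGGCATTGACGGCATTGACGGCATTGACGGCATTGACGGCATTGAC": (0.4, 0.4),
            },
            depth=2000,
            error_rate=0.0,
            seed=11,
        )
        generate_cleaveseq_run(truth, out_dir=tmp_path)
        pairs = seqio.read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        table = seqio.process_run(pairs, truth.scheme)
        expected = __import__("cleavedrive.synthgen", fromlist=["x"]).generate_count_run(truth)

        def keyed(t):
            return {
                (r.core_seq, r.prefix, r.condition, str(r.replicate)): r.count
                for r in t.data.itertuples()
            }

        assert keyed(table) == keyed(expected)
        qc = table.qc
        assert qc["reads_in"] == qc["merged"] == qc["demultiplexed"] == qc["classified"]

    def test_no_read_assigned_twice(self, scheme, rng):
        # a classified read belongs to exactly one condition and prefix
        core = random_seq(rng, 50)
        b5, b3 = scheme.barcodes["plus"]
        merged = b5 + scheme.prefixes["Z"] + core + scheme.suffix + b3
        matches = [
            cond for cond in scheme.barcodes
            if demultiplex(merged, scheme) and demultiplex(merged, scheme)[0] == cond
        ]
        assert matches == ["plus"]
        cond, body = demultiplex(merged, scheme)
        labels = [
            lab for lab in scheme.prefixes
            if classify_prefix(body, scheme)[0] == lab
        ]
        assert labels == ["Z"]
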