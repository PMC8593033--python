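"""Junction extraction and read counting against a per-base CIGAR oracle."""

import warnings

import numpy as np
import pytest

from splicenrich import SpliceEvent, TranscriptModel
from splicenrich.discovery import (
    build_count_matrix,
    count_boundary,
    count_congruent,
    count_sample,
    count_spanning,
    deduplicate,
    extract_junctions,
)
from splicenrich.simulate import SimConfig, SimRead, simulate_run

_OPS = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "=": 7, "X": 8}


def read(pos1, cigar, contig="chr1", flag=0, qname="q", mapq=60, seq=None, **kw):
    """Build a SimRead from a 1-based position and a CIGAR string."""
    tuples = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            tuples.append((_OPS[ch], int(num)))
            num = ""
    return SimRead(qname, flag, contig, pos1 - 1, tuples, query_sequence=seq, mapping_quality=mapq, **kw)


# -- independent oracle: expand every CIGAR into explicit positions ------

def _expand(r):
    """(aligned positions, gap intervals, span) of a read, all 1-based."""
    aligned, gaps = set(), []
    pos = r.reference_start + 1
    span_start = pos
    for op, length in r.cigartuples:
        if op in (0, 7, 8):
            aligned.update(range(pos, pos + length))
            pos += length
        elif op == 2:  # deletion: reference consumed, no aligned base
            pos += length
        elif op == 3:
            gaps.append((pos, pos + length - 1))
            pos += length
    return aligned, gaps, (span_start, pos - 1)


def oracle_counts(reads, event):
    r = s = b = 0
    for rd in reads:
        if rd.is_unmapped or rd.is_secondary or rd.is_supplementary:
            continue
        if rd.reference_name != event.contig:
            continue
        aligned, gaps, (start, end) = _expand(rd)
        if (event.intron_start, event.intron_end) in gaps:
            r += 1
        if start < event.intron_start <= end:
            s += 1
        if event.intron_start - 1 in aligned:
            b += 1
    return r, s, b


class TestExtractJunctions:
    def test_single_gap_coordinates(self):
        events = extract_junctions([read(1001, "50M100N50M")])
        assert events == {SpliceEvent("chr1", 1051, 1150): 1}

    def test_read_with_two_gaps_contributes_to_two_events(self):
        events = extract_junctions([read(1001, "30M10N30M20N30M")])
        assert events == {
            SpliceEvent("chr1", 1031, 1040): 1,
            SpliceEvent("chr1", 1071, 1090): 1,
        }

    def test_ungapped_read_yields_no_event(self):
        assert extract_junctions([read(1001, "100M")]) == {}

    def test_secondary_supplementary_unmapped_excluded(self):
        reads = [
            read(1001, "50M100N50M", flag=0x100),  # secondary
            read(1001, "50M100N50M", flag=0x800),  # supplementary (chimeric)
            read(1001, "50M100N50M", flag=0x4),  # unmapped
        ]
        stats = {}
        assert extract_junctions(reads, stats=stats) == {}
        assert stats["skipped"] == 3

    def test_soft_clips_do_not_shift_gap_coordinates(self):
        assert extract_junctions([read(1001, "10S40M100N50M10S")]) == {
            SpliceEvent("chr1", 1041, 1140): 1
        }


class TestCountingRules:
    EVENT = SpliceEvent("chr1", 1051, 1150)

    def test_congruent_requires_exact_gap(self):
        reads = [read(1001, "50M100N50M")] * 5 + [read(1001, "50M99N50M")] * 3
        assert count_congruent(reads, self.EVENT) == 5

    def test_indels_elsewhere_do_not_disqualify(self):
        # 10M2D40M consumes 52 reference bases: start at 999 so the gap
        # still opens at 1051
        r = read(999, "10M2D40M100N50M")
        assert count_congruent([r], self.EVENT) == 1

    def test_off_by_one_gap_not_congruent(self):
        assert count_congruent([read(1000, "50M101N50M")], self.EVENT) == 0

    def test_spanning_includes_plain_overlap(self):
        assert count_spanning([read(1001, "100M")], self.EVENT) == 1  # covers 1001-1100

    def test_spanning_includes_reads_gapping_over_the_site(self):
        # gap 940-1139 jumps over 1051 but the alignment spans 900-1179
        assert count_spanning([read(900, "40M200N40M")], self.EVENT) == 1

    def test_read_starting_at_intron_not_spanning(self):
        assert count_spanning([read(1051, "100M")], self.EVENT) == 0

    def test_read_ending_before_intron_not_spanning(self):
        assert count_spanning([read(951, "100M")], self.EVENT) == 0  # ends 1050

    def test_boundary_counts_aligned_base_at_donor(self):
        assert count_boundary([read(1001, "100M")], self.EVENT) == 1  # 1050 aligned

    def test_congruent_read_carries_boundary_base(self):
        assert count_boundary([read(1001, "50M100N50M")], self.EVENT) == 1

    def test_read_gapping_over_donor_lacks_boundary_base(self):
        assert count_boundary([read(900, "40M200N40M")], self.EVENT) == 0

    def test_deletion_spanning_donor_lacks_boundary_base(self):
        # deletion 1041-1060 covers 1050: reference consumed, no aligned base
        assert count_boundary([read(1001, "40M20D40M")], self.EVENT) == 0


class TestDeduplicate:
    def test_identical_fragments_collapse_to_one(self):
        reads = [read(1001, "100M", qname=f"q{i}") for i in range(3)]
        assert len(list(deduplicate(reads, "identical"))) == 1

    def test_distinct_umis_both_retained(self):
        class Tagged(SimRead):
            def __init__(self, umi, **kw):
                super().__init__(**kw)
                self._umi = umi

            def has_tag(self, tag):
                return tag == "RX"

            def get_tag(self, tag):
                return self._umi

        base = dict(flag=0, reference_name="chr1", reference_start=1000,
                    cigartuples=[(0, 100)])
        reads = [Tagged("AAA", query_name="a", **base), Tagged("CCC", query_name="b", **base)]
        assert len(list(deduplicate(reads, "umi"))) == 2

    def test_umi_mode_without_tag_is_error(self):
        with pytest.raises(ValueError, match="UMI"):
            list(deduplicate([read(1001, "100M")], "umi"))

    def test_none_mode_is_passthrough(self):
        reads = [read(1001, "100M", qname=f"q{i}") for i in range(3)]
        assert len(list(deduplicate(reads, "none"))) == 3


class TestCountMatrix:
    def test_union_semantics_across_samples(self):
        run = {
            "A": [read(1001, "50M100N50M"), read(990, "100M")],
            "B": [read(995, "100M"), read(1000, "100M")],
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = build_count_matrix(run)
        row_b = mat[(mat.sample_id == "B")].iloc[0]
        assert (row_b.r, row_b.s) == (0, 2)  # B never splices but spans the site

    def test_empty_alignments_warn_and_yield_zero_rows(self):
        with pytest.warns(UserWarning, match="no splice junctions"):
            mat = build_count_matrix({"A": [], "B": [], "C": [], "D": []})
        assert len(mat) == 0

    def test_small_group_warns(self):
        with pytest.warns(UserWarning, match="at least 4"):
            build_count_matrix({"A": [read(1001, "50M100N50M")]})

    def test_r_never_exceeds_s_on_simulated_runs(self, model8):
        cfg = SimConfig(model=model8, n_samples=4, depth=300, with_sequence=False,
                        spikes=[("S1", "skip(3)", 0.3)],
                        natural_events=[("alt_acceptor(5, 12)", 0.1)], seed=7)
        run = simulate_run(cfg)
        mat = build_count_matrix(run.reads)
        assert (mat.r <= mat.s).all()
        assert (mat.groupby(["contig", "intron_start", "intron_end"]).r.max() >= 1).all()


class TestOracleEquivalence:
    """Fast-path counts must equal the brute-force per-base expansion."""

    def _random_reads(self, rng, n):
        reads = []
        for i in range(n):
            pos = int(rng.integers(900, 1300))
            pieces = [(0, int(rng.integers(10, 80)))]
            while rng.random() < 0.5 and len(pieces) < 5:
                op = int(rng.choice([2, 3, 3, 1]))
                pieces.append((op, int(rng.integers(2, 150))))
                pieces.append((0, int(rng.integers(10, 80))))
            reads.append(SimRead(f"r{i}", 0, "chr1", pos, pieces))
        return reads

    def test_counts_match_oracle_on_random_reads(self):
        rng = np.random.default_rng(2024)
        for trial in range(8):
            reads = self._random_reads(rng, 50)
            events = list(extract_junctions(reads)) or [SpliceEvent("chr1", 1000, 1100)]
            fast = count_sample(reads, events)
            for ev in events:
                assert fast[ev] == oracle_counts(reads, ev), ev

    def test_standalone_counters_match_oracle(self):
        rng = np.random.default_rng(7)
        reads = self._random_reads(rng, 40)
        for ev in list(extract_junctions(reads))[:10]:
            assert count_congruent(reads, ev) == oracle_counts(reads, ev)[0]
            assert count_spanning(reads, ev) == oracle_counts(reads, ev)[1]
            assert count_boundary(reads, ev) == oracle_counts(reads, ev)[2]
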