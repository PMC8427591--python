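import numpy as np
import pytest

from _oracles import NoCore, naive_consensus, oracle_consensus, random_alignment
from cotupipe.cotu import (Call, ColumnProfile, CotuParams, call_column,
                           column_profiles, cotu_consensus, cotu_pipeline,
                           find_core_range)
from cotupipe.errors import InsufficientDepthError, NoCoreError
from cotupipe.io_formats import SeqRecord
from cotupipe.readgroup import Alignment, ClusterParams
from cotupipe.simulate import inject_errors, simulate_ragged_alignment


def _aln(*rows):
    return Alignment([f"r{i}" for i in range(len(rows))], list(rows))


def _profile(position, n_reads, **counts):
    full = {"A": 0, "C": 0, "G": 0, "T": 0, "other": 0, "gap": 0}
    full.update(counts)
    return ColumnProfile(position, full, n_reads)


class TestFindCoreRange:
    def test_full_coverage_spans_everything(self):
        aln = _aln(*["ACGTACGT"] * 10)
        core = find_core_range(aln, CotuParams(min_depth=1))
        assert (core.start, core.end) == (0, 7)

    def test_low_coverage_head_shifts_start(self):
        rows = ["--ACGTACGT"] * 7 + ["CCACGTACGT"] * 3
        core = find_core_range(_aln(*rows), CotuParams(min_depth=1))
        assert core.start == 2 and core.end == 9

    def test_no_qualifying_window(self):
        rows = ["AC--", "--GT", "A--T", "-C-T"]  # max coverage 50% of 4 reads
        with pytest.raises(NoCoreError):
            find_core_range(_aln(*rows), CotuParams(min_depth=1))


class TestCallColumn:
    def test_noise_base_removed_before_majority(self):
        call = call_column(_profile(0, 100, A=95, G=4, gap=1), in_core=True)
        assert call == Call("base", "A", 95 / 99)

    def test_gap_majority_is_insertion(self):
        call = call_column(_profile(0, 10, A=1, gap=9), in_core=True)
        assert call.kind == "drop_insertion"

    def test_end_region_at_threshold_is_normal(self):
        call = call_column(_profile(0, 10, C=3, gap=7), in_core=False)
        assert call == Call("base", "C", 1.0)

    def test_end_region_below_threshold_dropped(self):
        call = call_column(_profile(0, 10, C=1, gap=9), in_core=False)
        assert call.kind == "drop_end"

    def test_tie_emits_ambiguity_code(self):
        call = call_column(_profile(0, 10, A=5, G=5), in_core=True)
        assert call == Call("base", "R", 1.0)

    def test_gap_base_tie_keeps_base(self):
        call = call_column(_profile(0, 10, T=5, gap=5), in_core=True)
        assert call == Call("base", "T", 1.0)

    def test_optional_ambiguity_fraction(self):
        params = CotuParams(ambiguity_fraction=0.30)
        call = call_column(_profile(0, 10, C=6, T=4), in_core=True, params=params)
        assert call.base == "Y"
        call = call_column(_profile(0, 10, C=8, T=2), in_core=True, params=params)
        assert call.base == "C"


class TestCotuConsensus:
    def test_identical_rows(self):
        res = cotu_consensus(_aln(*["ACGT"] * 10))
        assert res.seq.seq == "ACGT"
        assert res.support == [1.0] * 4
        assert res.depth_used == 10

    def test_occasional_insertion_dropped(self):
        rows = ["ACAC-GTGT"] * 9 + ["ACACTGTGT"]
        res = cotu_consensus(_aln(*rows))
        assert res.seq.seq == "ACACGTGT"
        assert res.dropped_insertion_columns == 1

    def test_end_extension_beyond_majority_cutoff(self):
        # 3 of 10 reads extend 5 columns left of the core with agreeing bases:
        # the end threshold (20%) keeps them, a 50%-cutoff consensus does not
        rng = np.random.default_rng(5)
        aln, truth = simulate_ragged_alignment(rng, n_reads=10, core_len=30,
                                               left_ext=5, right_ext=0,
                                               left_cov=0.3, right_cov=0.0)
        res = cotu_consensus(aln)
        assert res.seq.seq == truth
        assert len(res.seq.seq) == len(naive_consensus(aln.rows)) + 5

    def test_insufficient_depth(self):
        with pytest.raises(InsufficientDepthError):
            cotu_consensus(_aln(*["ACGT"] * 5))

    def test_read_cap_uses_first_rows(self):
        rows = ["AAAA"] * 10 + ["CCCC"] * 100
        res = cotu_consensus(_aln(*rows), CotuParams(min_depth=5, max_reads=10))
        assert res.seq.seq == "AAAA" and res.depth_used == 10

    def test_deterministic(self, rng):
        rows = random_alignment(rng, max_rows=15, max_cols=40)
        params = CotuParams(min_depth=1)
        try:
            a = cotu_consensus(_aln(*rows), params)
            b = cotu_consensus(_aln(*rows), params)
        except NoCoreError:
            return
        assert (a.seq.seq, a.support, a.core) == (b.seq.seq, b.support, b.core)

    def test_matches_brute_force_oracle(self, rng):
        params = CotuParams(min_depth=1)
        checked = 0
        for _ in range(200):
            rows = random_alignment(rng)
            aln = _aln(*rows)
            try:
                expected = oracle_consensus(rows)
            except NoCore:
                with pytest.raises(NoCoreError):
                    cotu_consensus(aln, params)
                continue
            res = cotu_consensus(aln, params)
            seq, core, d_ins, d_end = expected
            assert res.seq.seq == seq
            assert (res.core.start, res.core.end) == core
            assert (res.dropped_insertion_columns, res.dropped_end_columns) == \
                (d_ins, d_end)
            checked += 1
        assert checked > 50

    def test_end_extension_never_shorter_than_majority_cutoff(self, rng):
        for _ in range(50):
            aln, _ = simulate_ragged_alignment(
                rng, n_reads=int(rng.integers(10, 20)),
                core_len=int(rng.integers(10, 40)),
                left_ext=int(rng.integers(0, 8)),
                right_ext=int(rng.integers(0, 8)),
                left_cov=float(rng.uniform(0.05, 0.95)),
                right_cov=float(rng.uniform(0.05, 0.95)))
            res = cotu_consensus(aln, CotuParams(min_depth=1))
            assert len(res.seq.seq) >= len(naive_consensus(aln.rows))

    def test_recovers_truth_from_noisy_alignments(self, rng):
        """Depth-50 alignments at 1% substitution / 0.1% indel rebuild the
        exact truth in >= 99 of 100 replicates."""
        from cotupipe.readgroup import center_star_align
        truth = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        ok = 0
        for _ in range(100):
            reads = [SeqRecord(f"r{i}", inject_errors(truth, rng, 0.01, 0.001)[0])
                     for i in range(50)]
            aln = center_star_align(reads)
            res = cotu_consensus(aln, CotuParams(min_depth=10, max_reads=500))
            ok += res.seq.seq == truth
        assert ok >= 99


class TestCotuPipeline:
    def test_shallow_bin_skipped(self):
        reads = [SeqRecord(f"r{i}", "ACGTACGTACGTACGTACGT") for i in range(5)]
        out = cotu_pipeline(reads)
        assert out.results == [] and out.skipped == [5]

    def test_two_species_mixture(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        b = list(a)
        for pos in rng.choice(150, 15, replace=False):
            b[pos] = "ACGT"["ACGT".index(b[pos]) - 1]
        b = "".join(b)
        reads = [SeqRecord(f"a{i}", a) for i in range(30)] + \
                [SeqRecord(f"b{i}", b) for i in range(20)]
        out = cotu_pipeline(reads, ClusterParams(0.97))
        assert [r.seq.seq for r in out.results] == [a, b]

    def test_deep_clean_bin_reproduces_reference(self, rng):
        truth = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        reads = [SeqRecord(f"r{i}", truth) for i in range(100)]
        out = cotu_pipeline(reads, ClusterParams(0.97))
        assert len(out.results) == 1
        assert out.results[0].seq.seq == truth
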