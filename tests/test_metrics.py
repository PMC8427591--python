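import math

import numpy as np
import pytest

from cotupipe.cotu import cotu_consensus
from cotupipe.errors import SaturatedDistanceError
from cotupipe.io_formats import SeqRecord
from cotupipe.metrics import (k2p_distance, recovery_percent,
                              site_error_profile, summarize_run)
from cotupipe.readgroup import Alignment


def _pair_with(sites, transitions, transversions):
    """Equal-length pair realising exact transition/transversion counts."""
    a = ["A"] * sites
    b = ["A"] * sites
    for i in range(transitions):
        b[i] = "G"                      # A->G transition
    for i in range(transitions, transitions + transversions):
        b[i] = "T"                      # A->T transversion
    return "".join(a), "".join(b)


class TestK2P:
    def test_identical_sequences(self):
        res = k2p_distance("ACGTACGT", "ACGTACGT", aligned=True)
        assert res.d == 0.0 and res.sites == 8

    def test_closed_form_ten_transitions(self):
        a, b = _pair_with(100, 10, 0)
        res = k2p_distance(a, b, aligned=True)
        assert res.P == 0.10 and res.Q == 0.0
        assert res.d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert res.d == pytest.approx(0.111572, abs=5e-7)

    @pytest.mark.parametrize("P,Q", [(0.0, 0.1), (0.05, 0.05), (0.2, 0.1),
                                     (0.01, 0.0), (0.0, 0.0)])
    def test_closed_form_grid(self, P, Q):
        sites = 1000
        a, b = _pair_with(sites, int(P * sites), int(Q * sites))
        res = k2p_distance(a, b, aligned=True)
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert res.d == pytest.approx(expected, abs=1e-12)

    def test_small_p_first_order_limit(self):
        a, b = _pair_with(1000, 10, 0)  # P = 0.01
        res = k2p_distance(a, b, aligned=True)
        assert res.d == pytest.approx(0.01, rel=0.05)

    def test_ambiguous_sites_ignored(self):
        a = "NNNNN" + "A" * 95
        b = "ACGTA" + "A" * 95
        res = k2p_distance(a, b, aligned=True)
        assert res.sites == 95 and res.d == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
            try:
                ra = k2p_distance(a, b, aligned=True)
                rb = k2p_distance(b, a, aligned=True)
            except SaturatedDistanceError:
                continue
            assert ra.d == pytest.approx(rb.d)

    def test_unaligned_inputs_get_aligned(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTCGTACGTACGT"  # one deletion relative to a
        res = k2p_distance(a, b)
        assert res.d == 0.0 and res.sites == 19

    def test_saturated_distance(self):
        a, b = _pair_with(100, 50, 0)
        with pytest.raises(SaturatedDistanceError):
            k2p_distance(a, b, aligned=True)

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            k2p_distance("NNNN", "ACGT", aligned=True)


class TestSiteErrorProfile:
    def test_error_free_reads(self):
        aln = Alignment(["ref", "a", "b"], ["ACGT", "ACGT", "ACGT"])
        prof = site_error_profile(aln, "ref")
        assert prof.match_rank == [1, 1, 1, 1]
        assert prof.accuracy == 1.0

    def test_majority_mismatch_ranks_second(self):
        # 3 of 5 reads carry G where the reference has A: rank 2 at that site
        rows = ["A", "G", "G", "G", "A", "A"]
        aln = Alignment(["ref", "r1", "r2", "r3", "r4", "r5"], rows)
        prof = site_error_profile(aln, "ref")
        assert prof.match_rank == [2]
        assert prof.frequencies.loc[0, "G"] == pytest.approx(0.6)
        assert prof.accuracy == 0.0

    def test_frequencies_are_distributions(self, rng):
        from cotupipe.simulate import inject_errors
        from cotupipe.readgroup import center_star_align
        truth = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        reads = [SeqRecord("ref", truth)] + [
            SeqRecord(f"r{i}", inject_errors(truth, rng, 0.05, 0.01)[0])
            for i in range(8)]
        aln = center_star_align(reads)
        prof = site_error_profile(aln, "ref")
        sums = prof.frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert len(prof.positions) == len(truth)

    def test_reference_gap_columns_skipped(self):
        aln = Alignment(["ref", "a"], ["AC-T", "ACGT"])
        prof = site_error_profile(aln, "ref")
        assert prof.positions == [0, 1, 2] and prof.reference == "ACT"

    def test_missing_reference(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            site_error_profile(aln, "ref")

    def test_no_reads(self):
        with pytest.raises(ValueError):
            site_error_profile(Alignment(["ref"], ["ACGT"]), "ref")


class TestRunSummary:
    def test_recovery_arithmetic(self):
        assert recovery_percent(350, 380) == 92.1
        assert recovery_percent(380, 380) == 100.0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            recovery_percent(10, 0)

    def test_summary_tables(self):
        import pandas as pd
        aln_rows = ["ACGTACGTAC"] * 10
        res = cotu_consensus(Alignment([f"r{i}" for i in range(10)], aln_rows))
        sets = {("s1", "g"): [res], ("s2", "g"): [res], ("s3", "g"): []}
        demux = pd.DataFrame({
            "sample": ["s1", "s2", "s3"], "gene": ["g"] * 3,
            "reads": [60, 30, 10]})
        summary = summarize_run(sets, n_samples=3, demux_summary=demux)
        row = summary.recovery.iloc[0]
        assert row["created"] == 2
        assert row["recovery_percent"] == pytest.approx(66.7)
        assert summary.lengths.iloc[0]["mean_len"] == 10.0
        per_gene = summary.depth_percent.groupby("gene")["percent"].sum()
        assert np.allclose(per_gene.values, 100.0)
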