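"""Reference annotation, bisulfite-aware alignment, calling, QC filtering."""

import numpy as np
import pytest

from rdnameth import (
    AmpliconReference,
    align_read,
    call_read_profile,
    call_reads,
    filter_reads,
    prepare_reference,
)
from rdnameth.amplicon import MISSING, ReadProfiles
from rdnameth.errors import ReferenceSpecError


def _mini_ref(sequence, cpgs, variant):
    return AmpliconReference("m", "mini", sequence, tuple(cpgs), variant)


class TestPrepareReference:
    def test_partitions_cytosines(self):
        ann = prepare_reference(_mini_ref("ACGGTCATA", [1], 7))
        assert ann.cpg_positions.tolist() == [1]
        assert ann.noncpg_c_positions.tolist() == [5]

    def test_no_cytosines_at_all(self):
        ann = prepare_reference(_mini_ref("ATGATAA", [], 0))
        assert ann.cpg_positions.size == 0 and ann.noncpg_c_positions.size == 0

    @pytest.mark.parametrize(
        "seq,cpgs,variant",
        [
            ("CCGG", [0], 3),  # seq[1] is C, not G
            ("ACGT", [1], 1),  # variant inside a CpG
            ("ACGT", [1], 2),  # variant on the CpG's G
            ("ACGT", [2], 0),  # not a CpG C
        ],
    )
    def test_invalid_annotation_rejected(self, seq, cpgs, variant):
        with pytest.raises(ReferenceSpecError):
            _mini_ref(seq, cpgs, variant)


class TestAlignment:
    def test_identity_alignment(self, ann_small):
        ref = ann_small.sequence
        aln = align_read(ref, ann_small)
        assert aln.score == len(ref)
        assert (aln.ref_to_read == np.arange(len(ref))).all()

    def test_fully_converted_read_scores_as_identity(self, ann_small):
        """Bisulfite asymmetry: read T under reference C is a match."""
        aln = align_read(ann_small.sequence.replace("C", "T"), ann_small)
        assert aln.score == len(ann_small.sequence)
        assert (aln.ref_to_read == np.arange(len(ann_small.sequence))).all()

    def test_internal_deletion_scored_exactly(self, ann_small):
        ref = ann_small.sequence
        read = ref[:20] + ref[22:]
        aln = align_read(read, ann_small)
        assert aln.score == (len(ref) - 2) * 1 - 2 * 2
        assert (aln.ref_to_read == -1).sum() == 2

    def test_garbage_read_flagged_unalignable(self, ann_small):
        aln = align_read("G" * len(ann_small.sequence), ann_small)
        assert not aln.aligned

    def test_reverse_complement_scores_badly(self, ann_small):
        from Bio.Seq import Seq

        rc = str(Seq(ann_small.sequence).reverse_complement())
        assert not align_read(rc, ann_small).aligned


class TestCalling:
    def test_fully_methylated_perfectly_converted(self, ref_small, ann_small):
        read = list(ref_small.sequence)
        for i, b in enumerate(read):
            if b == "C" and i not in ref_small.cpg_positions:
                read[i] = "T"
        prof = call_read_profile(align_read("".join(read), ann_small), ann_small)
        assert (prof.cpg_calls == 1).all()
        assert prof.conversion_rate == 1.0
        assert prof.allele == "A"

    def test_exactly_95_percent_conversion_read(self):
        """A read converting 19 of 20 non-CpG cytosines sits exactly at the
        >95% boundary and must be rejected by the strict filter."""
        # build a reference with 1 CpG and 20 non-CpG cytosines
        seq = "A" + "CA" * 20 + "CG" + "TA"
        ref = AmpliconReference("b", "x", seq, (41,), len(seq) - 2)
        ann = prepare_reference(ref)
        assert len(ann.noncpg_c_positions) == 20
        read = list(seq.replace("C", "T"))
        read[41] = "C"  # methylated CpG
        read[1] = "C"  # one unconverted non-CpG C
        prof = call_read_profile(align_read("".join(read), ann), ann)
        assert prof.conversion_rate == pytest.approx(0.95)
        batch = ReadProfiles.from_profiles([prof])
        passing, tally = filter_reads(batch)
        assert len(passing) == 0 and tally["low_conversion"] == 1

    def test_variant_base_drives_allele_call(self, ref_small, ann_small):
        base = list(ref_small.sequence.replace("C", "T"))
        vpos = ref_small.variant_position
        for b, expect in (("G", "G"), ("A", "A"), ("C", "undetermined")):
            read = base.copy()
            read[vpos] = b
            prof = call_read_profile(align_read("".join(read), ann_small), ann_small)
            assert prof.allele == expect

    def test_other_base_at_cpg_gives_missing_call(self, ref_small, ann_small):
        p0 = ref_small.cpg_positions[0]
        read = list(ref_small.sequence.replace("C", "T"))
        read[p0] = "A"  # neither C (methylated) nor T (unmethylated)
        prof = call_read_profile(align_read("".join(read), ann_small), ann_small)
        assert prof.cpg_calls[0] == MISSING


class TestBatchCalling:
    def test_fast_path_matches_per_read_alignment(self, ref_small, ann_small, rng):
        """Vectorized equal-length calling agrees with full NW calling."""
        from rdnameth import derive_mixture_preset, simulate_dbs_reads

        p = derive_mixture_preset(20.0, 5.0, 0.85, n_cpgs=6)
        reads, ids, _ = simulate_dbs_reads(
            ref_small, p, p, 30, conversion_failure=0.02, seq_error=0.01, seed=4
        )
        batch, n_un = call_reads(reads, ann_small, read_ids=ids)
        assert n_un == 0
        for i, prof in enumerate(batch):
            slow = call_read_profile(
                align_read(reads[i].tobytes().decode(), ann_small),
                ann_small,
                read_id=str(ids[i]),
            )
            assert (prof.cpg_calls == slow.cpg_calls).all()
            assert prof.allele == slow.allele
            assert prof.n_converted == slow.n_converted

    def test_length_mismatch_goes_through_nw(self, ref_small, ann_small):
        full = ref_small.sequence.replace("C", "T")
        short = full[:10] + full[12:]
        batch, n_un = call_reads([("a", full), ("b", short)], ann_small)
        assert len(batch) == 2 and n_un == 0

    def test_calls_match_simulation_truth_exactly(self, ref_region2):
        """With no conversion failure and no sequencing error, called CpG
        states equal the generator's ground truth for every read."""
        from rdnameth import builtin_preset, simulate_dbs_reads

        p = builtin_preset("region2", "A", "old")
        reads, ids, truth = simulate_dbs_reads(ref_region2, p, p, 200, 0.0, 0.0, seed=6)
        ann = prepare_reference(ref_region2)
        batch, _ = call_reads(reads, ann, read_ids=ids)
        assert (batch.calls != MISSING).all()
        np.testing.assert_array_equal(batch.calls.astype(bool), truth.methylation)
        assert (batch.alleles == truth.reads["allele"].to_numpy()).all()


class TestFilterReads:
    def test_tally_partitions_input(self, ref_region2):
        from rdnameth import builtin_preset, simulate_dbs_reads

        p = builtin_preset("region2", "G", "young")
        reads, ids, _ = simulate_dbs_reads(
            ref_region2, p, p, 2000, conversion_failure=0.02, seq_error=0.005, seed=8
        )
        ann = prepare_reference(ref_region2)
        batch, _ = call_reads(reads, ann, read_ids=ids)
        passing, tally = filter_reads(batch)
        assert tally["passed"] == len(passing)
        assert sum(tally.values()) == len(batch)
        assert (passing.conversion_rates > 0.95).all()

    def test_empty_input_is_not_an_error(self, ann_small):
        empty = ReadProfiles(
            read_ids=np.array([], dtype=object),
            alleles=np.array([], dtype="U1"),
            calls=np.zeros((0, 6), dtype=np.int8),
            n_noncpg_c_sites=np.array([], dtype=np.int64),
            n_converted=np.array([], dtype=np.int64),
        )
        passing, tally = filter_reads(empty)
        assert len(passing) == 0 and tally["passed"] == 0

    def test_undetermined_alleles_tallied_separately(self, ref_small, ann_small):
        read = ref_small.sequence.replace("C", "T")
        read = read[: ref_small.variant_position] + "T" + read[ref_small.variant_position + 1:]
        batch, _ = call_reads([("u1", read), ("u2", read)], ann_small)
        passing, tally = filter_reads(batch)
        assert len(passing) == 0 and tally["undetermined_allele"] == 2
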