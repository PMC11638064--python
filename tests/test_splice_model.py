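"""Branchpoint enumeration, disruption calls and cryptic-acceptor scanning."""

import numpy as np
import pytest

from branchretain import splice_model as sm
from branchretain.gene_model import reverse_complement

PY = set("CT")


def brute_force_rank(intron_seq, window):
    """Independent oracle: enumerate window A's, score by explicit rules, sort."""
    seq = intron_seq.upper()
    L = len(seq)
    rows = []
    for off in range(window[0], window[1] + 1):
        i = L - off
        if seq[i] != "A":
            continue
        score = 0.0
        if i - 2 >= 0 and seq[i - 2] in PY:
            score += 0.25
        if i - 1 >= 0 and seq[i - 1] == "T":
            score += 0.5
        if i + 1 < L and seq[i + 1] in PY:
            score += 0.25
        rows.append((off, score))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows


def make_intron(tail, length=100):
    """Intron in transcript orientation: GT donor + C filler + given 3' tail."""
    assert length >= len(tail) + 2
    return "GT" + "C" * (length - 2 - len(tail)) + tail


class TestEnumerate:
    def test_unique_perfect_candidate_scores_one(self):
        # single A in window at offset 34 with uUuAu context
        tail = "TTAT" + "C" * 30 + "AG"  # offsets 36..33, filler 32..3, acceptor
        intron = make_intron(tail)
        cands = sm.enumerate_branchpoints(intron)
        assert len(cands) == 1
        assert cands[0].offset == 34 and cands[0].motif_score == 1.0

    def test_reference_geometry_default_locus(self, locus):
        cands = sm.enumerate_branchpoints(locus.focal_intron_seq())
        assert cands[0].offset == 34 and cands[0].motif_score == 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_ranking_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "GT" + "".join(rng.choice(list("ACGT"), 80)) + "AG"
        window = (18, 44)
        got = [(c.offset, c.motif_score) for c in sm.enumerate_branchpoints(seq, window)]
        assert got == brute_force_rank(seq, window)

    def test_no_a_in_window_gives_empty_list(self):
        seq = make_intron("C" * 50 + "AG")
        assert sm.enumerate_branchpoints(seq) == []

    def test_bad_acceptor_rejected(self):
        with pytest.raises(ValueError):
            sm.enumerate_branchpoints("GT" + "C" * 60 + "AT")


class TestVariantEffect:
    def test_a_to_c_at_top_candidate_disrupts(self, locus):
        cands = sm.enumerate_branchpoints(locus.focal_intron_seq())
        disrupted, alt = sm.assess_variant_effect(cands, 34, "A", "C")
        assert disrupted
        assert alt is None or alt.offset != 34

    def test_variant_off_candidate_not_disruptive(self, locus):
        cands = sm.enumerate_branchpoints(locus.focal_intron_seq())
        disrupted, _ = sm.assess_variant_effect(cands, 20, "A", "G")
        assert not disrupted

    def test_tie_case_alt_bp_is_the_other_candidate(self):
        # two A's with identical perfect contexts at offsets 25 and 34;
        # proximity tie-break ranks 25 first, variant destroys it
        tail = "TTAT" + "CCCCC" + "TTAT" + "C" * 21 + "AG"
        intron = make_intron(tail)
        cands = sm.enumerate_branchpoints(intron)
        oracle = brute_force_rank(intron, (18, 44))
        assert [(c.offset, c.motif_score) for c in cands] == oracle
        assert cands[0].offset == 25 and cands[0].motif_score == cands[1].motif_score
        disrupted, alt = sm.assess_variant_effect(cands, 25, "A", "C")
        assert disrupted and alt.offset == 34


class TestCrypticScan:
    def test_reference_geometry_gap6_retained39(self, locus):
        acc, retained = sm.scan_cryptic_acceptor(locus.focal_intron_seq(), 34)
        assert acc == 40 and retained == 39
        assert acc - 34 == 6

    def test_ag_adjacent_to_branchpoint(self):
        # AG at offsets 36/35, branchpoint at 34
        tail = "CCAG" + "A" + "T" + "C" * 30 + "AG"  # offsets 38..35, 34, 33, ...
        intron = make_intron(tail)
        acc, retained = sm.scan_cryptic_acceptor(intron, 34)
        assert acc == 35 and retained == 34

    def test_no_upstream_ag_returns_absent(self):
        intron = make_intron("T" * 32 + "A" + "T" * 9 + "AG")
        # everything 5' of the branchpoint is T/C filler or the GT donor: no AG
        acc, retained = sm.scan_cryptic_acceptor(intron, 10)
        if acc is not None:
            # guard: the constructed sequence truly has no upstream AG
            pytest.fail(f"unexpected AG at offset {acc}")
        assert retained is None

    def test_retained_segment_excludes_ag_abuts_exon(self, locus):
        """Retained segment = offsets (acc-1)..1: never includes the AG, always
        ends at the intron/exon boundary."""
        call = locus.splice_call()
        assert call.retained_len == call.cryptic_acceptor - 1

    @pytest.mark.parametrize("seed", range(20))
    def test_scan_matches_linear_search_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "GT" + "".join(rng.choice(list("ACGT"), 80)) + "AG"
        bp = 30
        acc, retained = sm.scan_cryptic_acceptor(seq, bp)
        # oracle: check offsets one by one
        L = len(seq)
        expect = None
        for g in range(bp + 1, L):
            if seq[L - g].upper() == "G" and seq[L - g - 1].upper() == "A":
                expect = g
                break
        assert acc == expect
        if expect is not None:
            assert retained == expect - 1


class TestFullCall:
    def test_disrupted_false_gives_canonical_only(self, locus):
        call = sm.call_splice_disruption(locus.focal_intron_seq(), 34, "A", "A")
        assert not call.disrupted and call.predicted_isoforms == {"canonical"}

    def test_no_acceptor_gives_full_retention_only(self):
        tail = "TTAT" + "C" * 30 + "AG"
        intron = make_intron(tail)
        call = sm.call_splice_disruption(intron, 34, "A", "C")
        assert call.disrupted and call.cryptic_acceptor is None
        assert call.predicted_isoforms == {"canonical", "full_retention"}

    def test_strand_invariance(self, locus, plus_locus):
        for loc in (locus, plus_locus):
            call = loc.splice_call()
            assert (call.primary_bp.offset, call.cryptic_acceptor, call.retained_len) == (
                34,
                40,
                39,
            )


class TestPredictIsoforms:
    def test_partial_first_retained_base_39nt_before_downstream_exon(self, locus):
        call = locus.splice_call()
        iso = sm.predict_isoforms(locus.gene, call)
        fs, fe = locus.gene.focal_intron()
        partial = iso["partial_retention"]
        # minus strand: downstream exon ends at fs; retained block is [fs, fs+39)
        covered = set()
        for s, e in partial:
            covered.update(range(s, e))
        retained_in_intron = sorted(set(range(fs, fe)) & covered)
        assert len(retained_in_intron) == 39
        assert retained_in_intron[0] == fs  # abuts the downstream exon

    def test_partial_blocks_subset_of_full_union_canonical(self, locus):
        call = locus.splice_call()
        iso = sm.predict_isoforms(locus.gene, call)

        def positions(blocks):
            out = set()
            for s, e in blocks:
                out.update(range(s, e))
            return out

        assert positions(iso["partial_retention"]) <= positions(iso["full_retention"]) | positions(
            iso["canonical"]
        )

    def test_generator_self_consistency(self, locus):
        """The read generator's partial isoform is built from this module's call."""
        from branchretain import synthetic_data as syn

        reads = syn.simulate_cohort_reads(
            syn.CohortSpec(
                seed=0,
                n_per_genotype={"GG": 1, "GT": 0, "TT": 0},
                retention_rates={"G": (1.0, 0.0), "T": (0.0, 0.0)},
                depth_per_sample=20,
                truncation_per_kb=0.0,
            ),
            locus,
        )
        call = locus.splice_call()
        fs, fe = locus.gene.focal_intron()
        for r in reads:
            assert r.isoform == "partial_retention"
            intronic = sum(max(0, min(e, fe) - max(s, fs)) for s, e in r.blocks)
            assert intronic == call.retained_len
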