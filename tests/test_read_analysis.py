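"""Allele assignment, purity, swap control, isoform classes, demux, methylation."""

import numpy as np
import pandas as pd
import pytest

from branchretain import coverage_quant as cq
from branchretain import read_analysis as ra
from branchretain import synthetic_data as syn
from branchretain.gene_model import Region, RegionRole, VariantSite, build_region_set


def _records(locus, spec):
    reads = syn.simulate_cohort_reads(spec, locus)
    return reads, [cq.AlignmentRecord.from_sim_read(r) for r in reads]


class TestAssignAllele:
    def setup_method(self):
        self.variant = VariantSite(pos=5, ref="T", alt="G")

    def _rec(self, seq, blocks=((0, 10),), quals=None):
        return cq.AlignmentRecord("r", "c", [tuple(b) for b in blocks], 60, 0, seq, quals)

    def test_risk_base(self):
        call = ra.assign_allele(self._rec("AAAAAGAAAA"), self.variant, "G", "T")
        assert call.allele == ra.RISK and call.base == "G"

    def test_nonrisk_base(self):
        call = ra.assign_allele(self._rec("AAAAATAAAA"), self.variant, "G", "T")
        assert call.allele == ra.NONRISK

    def test_read_ending_before_site_uncovered(self):
        call = ra.assign_allele(self._rec("AAAAA", blocks=[(0, 5)]), self.variant, "G", "T")
        assert call.allele == ra.UNCOVERED

    def test_n_base_is_other(self):
        call = ra.assign_allele(self._rec("AAAAANAAAA"), self.variant, "G", "T")
        assert call.allele == ra.OTHER

    def test_low_baseq_excluded_as_other_with_quality(self):
        quals = [30] * 5 + [5] + [30] * 4
        call = ra.assign_allele(
            self._rec("AAAAAGAAAA", quals=quals), self.variant, "G", "T", min_baseq=20
        )
        assert call.allele == ra.OTHER and call.baseq == 5


class TestHaplotypePurity:
    def test_zero_error_het_is_pure(self, locus):
        spec = syn.CohortSpec(seed=0, n_per_genotype={"GG": 0, "GT": 4, "TT": 0},
                              error_rate=0.0)
        reads, recs = _records(locus, spec)
        truth = {r.name: r.isoform for r in reads}
        calls = [
            ra.assign_allele(rec, locus.gene.variant_site, syn.RISK_ALLELE, syn.NONRISK_ALLELE)
            for rec in recs
            if truth[rec.read_id] != "canonical"
        ]
        res = ra.haplotype_purity(calls)
        assert res.defined and res.fraction_risk == 1.0

    def test_purity_on_truth_equals_purity_on_assigned(self, locus):
        """At zero error rate the assigned alleles reproduce the truth labels."""
        spec = syn.CohortSpec(seed=1, n_per_genotype={"GG": 1, "GT": 2, "TT": 1},
                              error_rate=0.0)
        reads, recs = _records(locus, spec)
        truth = {r.name: r for r in reads}
        for rec in recs:
            call = ra.assign_allele(
                rec, locus.gene.variant_site, syn.RISK_ALLELE, syn.NONRISK_ALLELE
            )
            if call.allele == ra.UNCOVERED:
                continue
            expect = ra.RISK if truth[rec.read_id].haplotype == syn.RISK_ALLELE else ra.NONRISK
            assert call.allele == expect

    def test_forced_retention_on_nonrisk_gives_zero_purity(self, locus):
        spec = syn.CohortSpec(
            seed=2, n_per_genotype={"GG": 0, "GT": 0, "TT": 2}, error_rate=0.0,
            retention_rates={"G": (0.0, 0.0), "T": (0.3, 0.1)},
        )
        reads, recs = _records(locus, spec)
        truth = {r.name: r.isoform for r in reads}
        calls = [
            ra.assign_allele(rec, locus.gene.variant_site, syn.RISK_ALLELE, syn.NONRISK_ALLELE)
            for rec in recs
            if truth[rec.read_id] != "canonical"
        ]
        res = ra.haplotype_purity(calls)
        assert res.defined and res.fraction_risk == 0.0

    def test_no_covered_reads_flagged_undefined(self):
        res = ra.haplotype_purity([ra.AlleleCall("r", ra.UNCOVERED, None)])
        assert not res.defined and res.fraction_risk is None


def brute_force_align_score(a, b, match=1, mismatch=-1, gap=-2):
    """O(len(a)*len(b)) Smith-Waterman with linear gap penalty."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best


class TestSwapControl:
    def test_compliant_pair_concordance_one(self, locus):
        spec = syn.CohortSpec(seed=3, n_per_genotype={"GG": 1, "GT": 1, "TT": 1},
                              depth_per_sample=40, error_rate=0.0)
        _, recs = _records(locus, spec)
        covering = [r for r in recs if r.base_at(locus.gene.variant_site.pos) is not None][:20]
        lo, hi = locus.gene.span
        plo, phi = locus.gene.paralog.span
        res = ra.allele_swap_control(
            covering, locus.gene.variant_site,
            locus.chrom_seq[lo:hi], locus.chrom_seq[plo:phi],
            syn.RISK_ALLELE, syn.NONRISK_ALLELE,
        )
        assert res.n_evaluated > 0
        assert res.concordance == 1.0 and res.warning is None

    def test_adversarial_pair_assignment_is_variant_driven(self):
        """Paralogs identical except at the variant-homologous site: flipping
        the base flips the best alignment, concordance < 1 with a warning."""
        rng = np.random.default_rng(0)
        gene = "".join(rng.choice(list("ACGT"), 120))
        pos = 60
        gene = gene[:pos] + "T" + gene[pos + 1 :]
        paralog = gene[:pos] + "G" + gene[pos + 1 :]
        read_seq = gene[40:80]
        rec = cq.AlignmentRecord("r", "c", [(40, 80)], 60, 0, read_seq, None)
        res = ra.allele_swap_control(
            [rec], VariantSite(pos=pos, ref="T", alt="G"), gene, paralog, "G", "T"
        )
        assert res.concordance is not None and res.concordance < 1.0
        assert res.warning is not None

    def test_read_without_distinguishing_site_flagged_ambiguous(self):
        gene = "ACGT" * 30
        paralog = gene[:100] + "TTTT" + gene[104:]  # differs only outside the read
        rec = cq.AlignmentRecord("r", "c", [(10, 40)], 60, 0, gene[10:40], None)
        # base at pos 22 is G; swapping G<->T leaves both references equally good
        res = ra.allele_swap_control(
            [rec], VariantSite(pos=22, ref="G", alt="T"), gene, paralog, "T", "G"
        )
        assert res.n_ambiguous == 1 and res.n_evaluated == 0 and res.concordance is None

    def test_missing_paralog_errors(self):
        rec = cq.AlignmentRecord("r", "c", [(0, 4)], 60, 0, "ACGT", None)
        with pytest.raises(ValueError):
            ra.allele_swap_control([rec], VariantSite(1, "C", "A"), "ACGT", None, "A", "C")

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_scores_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), 60))
        query = "".join(rng.choice(list("ACGT"), 25))
        got = ra._aligner().score(ref, query)
        assert got == brute_force_align_score(ref, query)


def interval_oracle(blocks, regions, min_overlap=0.8, min_intron_frac=0.9, max_canon=2):
    """Independent re-statement of the classification rules via plain set arithmetic."""
    pos = set()
    for s, e in blocks:
        pos.update(range(s, e))
    by = {r.role: set(range(r.start, r.end)) for r in regions}
    intron = by[RegionRole.INTRON_FULL]
    win = by[RegionRole.INTRON_SHORT_WINDOW]
    rest = by[RegionRole.INTRON_REST]
    f_intron = len(pos & intron) / len(intron)
    f_win = len(pos & win) / len(win)
    f_rest = len(pos & rest) / len(rest) if rest else 0.0
    has_down = bool(pos & by[RegionRole.EXON_DOWN])
    has_up = bool(pos & by[RegionRole.EXON_UP])
    if f_intron >= min_intron_frac and has_down:
        return ra.FULL
    if f_win >= min_overlap and has_down and f_rest < min_intron_frac:
        return ra.PARTIAL
    if has_up and has_down and len(pos & intron) <= max_canon:
        return ra.CANONICAL
    return ra.AMBIGUOUS


class TestClassifyIsoform:
    def test_junction_read_is_canonical(self, locus, regions):
        ex_up = next(r for r in regions if r.name == "exon_up")
        ex_down = next(r for r in regions if r.name == "exon_down")
        # minus strand: exon_down below the intron, exon_up above
        blocks = [(ex_down.end - 20, ex_down.end), (ex_up.start, ex_up.start + 20)]
        rec = cq.AlignmentRecord("r", locus.chrom, blocks, 60, 0, None, None)
        assert ra.classify_isoform(rec, regions).klass == ra.CANONICAL

    def test_read_starting_39nt_before_downstream_exon_is_partial(self, locus, regions):
        win = next(r for r in regions if r.name == "intron_short_window")
        ex_down = next(r for r in regions if r.name == "exon_down")
        blocks = [(ex_down.start, win.end)]  # contiguous: exon_down + 39-nt window
        rec = cq.AlignmentRecord("r", locus.chrom, blocks, 60, 0, None, None)
        assert ra.classify_isoform(rec, regions).klass == ra.PARTIAL

    def test_low_mapq_read_ambiguous(self, locus, regions):
        win = next(r for r in regions if r.name == "intron_short_window")
        rec = cq.AlignmentRecord("r", locus.chrom, [(win.start, win.end)], 10, 0, None, None)
        assert ra.classify_isoform(rec, regions).klass == ra.AMBIGUOUS

    def test_matches_interval_oracle_on_truth_reads(self, locus, regions):
        spec = syn.CohortSpec(seed=7, depth_per_sample=125, error_rate=0.0)
        reads = syn.simulate_cohort_reads(spec, locus, with_sequences=False)
        assert len(reads) == 1000
        agree = 0
        for r in reads:
            rec = cq.AlignmentRecord.from_sim_read(r)
            got = ra.classify_isoform(rec, regions).klass
            assert got == interval_oracle(r.blocks, regions)
            agree += 1
        assert agree == 1000

    def test_order_invariant_and_deterministic(self, locus, regions):
        spec = syn.CohortSpec(seed=8, depth_per_sample=20)
        reads = syn.simulate_cohort_reads(spec, locus, with_sequences=False)
        recs = [cq.AlignmentRecord.from_sim_read(r) for r in reads]
        fwd = [ra.classify_isoform(r, regions).klass for r in recs]
        rev = [ra.classify_isoform(r, regions).klass for r in reversed(recs)]
        assert fwd == rev[::-1]


class TestDemux:
    WL = ["AAAAAAAAAAAAAAAA", "CCCCCCCCCCCCCCCC", "GGGGGGGGGGGGGGGG"]

    def test_exact_match_assigned(self):
        res = ra.demux_barcodes([("r1", self.WL[0] + "TTTT")], self.WL)
        assert res.assignments[self.WL[0]] == ["r1"]

    def test_one_mismatch_assigned(self):
        bc = "AAAAAAAAAAAAAAAT"
        res = ra.demux_barcodes([("r1", bc + "GGGG")], self.WL)
        assert res.assignments[self.WL[0]] == ["r1"]

    def test_two_mismatches_unassigned(self):
        bc = "AAAAAAAAAAAAAATT"
        res = ra.demux_barcodes([("r1", bc)], self.WL)
        assert res.assignments["unassigned"] == ["r1"]

    def test_equidistant_between_two_entries_unassigned(self):
        wl = ["AAAA", "AATT"]
        # barcode AATA: Hamming 1 from both entries -> exhaustive scan agrees
        dists = [sum(a != b for a, b in zip("AATA", w)) for w in wl]
        assert dists == [1, 1]
        res = ra.demux_barcodes([("r1", "AATA")], wl, barcode_len=4)
        assert res.assignments["unassigned"] == ["r1"]

    def test_duplicate_whitelist_rejected(self):
        with pytest.raises(ValueError):
            ra.demux_barcodes([("r", "AAAA")], ["AAAA", "AAAA"])

    def test_whitelist_ratio(self):
        res = ra.demux_barcodes([("r1", self.WL[0]), ("r2", self.WL[0])], self.WL)
        assert res.observed_whitelist_ratio == pytest.approx(1 / 3)


class TestMethylationByAllele:
    def test_complete_separation_exact_p(self):
        # 10/10 methylated G vs 0/10 T: two-sided Fisher p = 2/C(20,10)
        df = pd.DataFrame(
            {"allele": ["G"] * 10 + ["T"] * 10, "methylated": [1] * 10 + [0] * 10}
        )
        res = ra.methylation_by_allele(df)
        assert res.fractions == {"G": 1.0, "T": 0.0}
        from math import comb

        assert res.p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_equal_fractions_p_one(self):
        df = pd.DataFrame(
            {"allele": ["G", "G", "T", "T"], "methylated": [1, 0, 1, 0]}
        )
        assert ra.methylation_by_allele(df).p == 1.0

    def test_single_allele_flagged_undefined(self):
        df = pd.DataFrame({"allele": ["G", "G"], "methylated": [1, 0]})
        res = ra.methylation_by_allele(df)
        assert not res.defined and res.p is None and res.fractions["G"] == 0.5

    def test_generator_recovery_within_3sd(self):
        mm = syn.MethylationModel(p_meth={"G": 0.9, "T": 0.1},
                                  calls_per_allele={"G": 500, "T": 500})
        df = syn.simulate_methylation_calls(mm, seed=3)
        res = ra.methylation_by_allele(df)
        for allele, p in [("G", 0.9), ("T", 0.1)]:
            sd = np.sqrt(p * (1 - p) / 500)
            assert abs(res.fractions[allele] - p) <= 3 * sd
        assert res.p < 1e-10
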