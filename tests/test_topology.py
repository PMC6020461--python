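"""Region assignment, enrichment ORs, contexts, metagene, conserved loci."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m5ctopo.formats_io import TranscriptModel
from m5ctopo.site_calling import CallResult, mratio
from m5ctopo.topology import (
    TranscriptIndex,
    assign_region,
    chromosome_enrichment,
    conserved_locus_association,
    context_proportion_correlation,
    context_table,
    enrichment_or,
    metagene_profile,
    region_enrichment,
)

from conftest import fisher_two_sided_oracle, make_site, single_exon_tx


def call_of(site, called=True, mr=None):
    return CallResult(
        site=site,
        mratio=mr if mr is not None else mratio(site.n_meth, max(1, site.n_unmeth)),
        pvalue=0.001 if called else 0.9,
        fdr=0.001 if called else 0.9,
        called=called,
    )


class TestAssignRegion:
    def test_ambiguous_site_splits_weight_evenly(self):
        # isoform 1: position 280 in 3'UTR; isoform 2 (longer CDS): in CDS
        t1 = single_exon_tx(tx_id="t1", gene_id="g", cds=(100, 250))
        t2 = single_exon_tx(tx_id="t2", gene_id="g", cds=(100, 290))
        idx = TranscriptIndex([t1, t2])
        w = assign_region("chr1", 280, idx)
        assert w == {"3UTR": 0.5, "CDS": 0.5}

    def test_single_isoform_full_weight(self):
        idx = TranscriptIndex([single_exon_tx()])
        assert assign_region("chr1", 150, idx) == {"CDS": 1.0}

    def test_three_isoforms_same_region_collapse_to_one(self):
        txs = [single_exon_tx(tx_id=f"t{i}", gene_id="g") for i in range(3)]
        idx = TranscriptIndex(txs)
        w = assign_region("chr1", 150, idx)
        assert w == {"CDS": pytest.approx(1.0)}

    def test_nonexonic_position_rejected(self):
        idx = TranscriptIndex([single_exon_tx()])
        with pytest.raises(ValueError):
            assign_region("chr1", 400, idx)

    def test_weights_always_sum_to_one(self):
        t1 = single_exon_tx(tx_id="a", cds=(100, 250))
        t2 = single_exon_tx(tx_id="b", cds=None)  # noncoding isoform
        idx = TranscriptIndex([t1, t2])
        for pos in (1, 50, 150, 260, 300):
            assert sum(assign_region("chr1", pos, idx).values()) == pytest.approx(1.0)


class TestEnrichmentOr:
    def test_hand_computed_ratio(self):
        er = enrichment_or(10, 100, 20, 400)
        assert er.odds_ratio == pytest.approx(2.0)

    def test_uniform_methylation_gives_unity(self):
        er = enrichment_or(5, 100, 25, 500)
        assert er.odds_ratio == pytest.approx(1.0)

    def test_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n_in = int(rng.integers(2, 14))
            n_out = int(rng.integers(2, 14))
            k_in = int(rng.integers(0, n_in + 1))
            k_out = int(rng.integers(0, n_out + 1))
            er = enrichment_or(k_in, n_in, k_in + k_out, n_in + n_out)
            oracle = fisher_two_sided_oracle(k_in, n_in - k_in, k_out, n_out - k_out)
            assert er.pvalue == pytest.approx(oracle, abs=1e-10)

    def test_or_invariant_under_common_scaling(self):
        base = enrichment_or(3, 30, 9, 300)
        scaled = enrichment_or(30, 300, 90, 3000)
        assert scaled.odds_ratio == pytest.approx(base.odds_ratio)
        assert scaled.pvalue <= base.pvalue  # more data, sharper test

    def test_zero_denominator_continuity_corrected(self):
        with pytest.warns(UserWarning):
            er = enrichment_or(0, 0, 5, 100)
        assert np.isfinite(er.odds_ratio)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_or(10, 5, 20, 400)


class TestRegionEnrichment:
    def test_weight_conservation_across_regions(self, small_dataset):
        cfg, data = small_dataset
        from m5ctopo.site_calling import call_sites

        calls = call_sites(data["replicates"]["rep1"])
        res = region_enrichment(calls, data["transcripts"])
        n_sum = sum(e.n_in for e in res)
        assert n_sum == pytest.approx(res[0].n_total)
        k_sum = sum(e.k_in for e in res)
        assert k_sum == pytest.approx(res[0].k_total)

    def test_constructed_utr5_enrichment_detected(self):
        t = single_exon_tx()  # 5UTR 0..100, CDS 100..250, 3UTR 250..300
        results = []
        for pos in range(1, 101):  # 5'UTR: half called
            results.append(call_of(make_site(pos=pos), called=pos % 2 == 0))
        for pos in range(101, 301):  # rest: rarely called
            results.append(call_of(make_site(pos=pos), called=pos % 20 == 0))
        res = {e.stratum: e for e in region_enrichment(results, [t])}
        assert res["5UTR"].odds_ratio > 2
        assert res["5UTR"].pvalue < 1e-6


class TestChromosomeEnrichment:
    def test_mito_like_excess_detected(self):
        results = [
            call_of(make_site(chrom="chrM", pos=p), called=p % 2 == 0) for p in range(1, 101)
        ] + [
            call_of(make_site(chrom="chr1", pos=p), called=p % 100 == 0)
            for p in range(1, 2001)
        ]
        res = {e.stratum: e for e in chromosome_enrichment(results)}
        assert res["chrM"].odds_ratio > 10
        assert res["chr1"].odds_ratio < 1


class TestContextTable:
    def _calls(self, contexts, called_mask):
        return [
            call_of(make_site(pos=i + 1, context=c), called=bool(m))
            for i, (c, m) in enumerate(zip(contexts, called_mask))
        ]

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        ctxs = [a + "C" + b for a in "ACGT" for b in "ACGT"]
        contexts = rng.choice(ctxs, size=400)
        called = rng.random(400) < 0.2
        tab = context_table(self._calls(contexts, called))
        assert tab.prop_called.sum() == pytest.approx(1.0)
        assert tab.prop_covered.sum() == pytest.approx(1.0)

    def test_cg_only_methylation_confined_to_cg_contexts(self):
        rng = np.random.default_rng(3)
        ctxs = [a + "C" + b for a in "ACGT" for b in "ACGT"]
        contexts = rng.choice(ctxs, size=600)
        called = np.array([c.endswith("G") and rng.random() < 0.5 for c in contexts])
        tab = context_table(self._calls(contexts, called))
        nonzero = set(tab[tab.prop_called > 0].context)
        assert nonzero <= {"ACG", "CCG", "GCG", "TCG"}

    def test_identical_samples_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        ctxs = [a + "C" + b for a in "ACGT" for b in "ACGT"]
        contexts = rng.choice(ctxs, size=500)
        called = rng.random(500) < 0.3
        tab = context_table(self._calls(contexts, called))
        assert context_proportion_correlation(tab, tab) == pytest.approx(1.0)


class TestMetagene:
    def _tx(self, strand="+"):
        # 5UTR 150, CDS 300, 3UTR 150; single exon 0..600
        if strand == "+":
            return single_exon_tx(length=600, cds=(150, 450), strand="+")
        return single_exon_tx(length=600, cds=(150, 450), strand="-")

    def test_first_base_of_cds_maps_to_one(self):
        t = self._tx("+")
        res = [call_of(make_site(pos=151))]  # 0-based 150 = CDS start
        prof = metagene_profile(res, [t], n_bins=300)
        bin_idx = int(np.argmax(prof.weight_called))
        assert prof.bin_left[bin_idx] == pytest.approx(1.0, abs=0.01)

    def test_mid_utr3_minus_strand_maps_to_2_5(self):
        t = self._tx("-")
        # '-' strand: genomic [0,150) is the 3'UTR read 3'->5'; its midpoint
        # in transcript orientation is coordinate 2.5
        res = [call_of(make_site(pos=75, strand="-"))]
        prof = metagene_profile(res, [t], n_bins=300)
        bin_idx = int(np.argmax(prof.weight_called))
        centre = (prof.bin_left[bin_idx] + prof.bin_right[bin_idx]) / 2
        assert centre == pytest.approx(2.5, abs=0.02)

    def test_histogram_masses_sum_to_one_per_class(self):
        t = self._tx("+")
        res = [call_of(make_site(pos=p), called=(p % 3 == 0)) for p in range(1, 601, 7)]
        prof = metagene_profile(res, [t])
        assert prof.weight_called.sum() == pytest.approx(1.0)
        assert prof.weight_background.sum() == pytest.approx(1.0)

    def test_short_region_transcripts_excluded(self):
        short = single_exon_tx(length=300, cds=(100, 250))  # 3'UTR only 50 nt
        with pytest.raises(ValueError):
            metagene_profile([call_of(make_site(pos=10))], [short])


class TestConservedLocusAssociation:
    def _identity_mapping(self, positions):
        return pd.DataFrame(
            {
                "chrom_a": "chr1", "pos_a": positions, "strand_a": "+",
                "chrom_b": "chr1", "pos_b": positions, "strand_b": "+",
            }
        )

    def test_identical_call_sets_maximal_association(self):
        rng = np.random.default_rng(5)
        pos = np.arange(1, 401)
        called = rng.random(400) < 0.3
        calls = [call_of(make_site(pos=int(p)), called=bool(c)) for p, c in zip(pos, called)]
        res = conserved_locus_association(calls, calls, self._identity_mapping(pos))
        assert res["all"].pvalue < 1e-20
        assert res["all"].table[0][1] == 0 and res["all"].table[1][0] == 0

    def test_table_matches_brute_force_oracle(self):
        # engineered calls giving table [[30,10],[10,50]]
        calls_a, calls_b, pos = [], [], []
        p = 1
        for a, b, n in (
            (True, True, 30), (True, False, 10), (False, True, 10), (False, False, 50)
        ):
            for _ in range(n):
                calls_a.append(call_of(make_site(pos=p), called=a))
                calls_b.append(call_of(make_site(pos=p), called=b))
                pos.append(p)
                p += 1
        res = conserved_locus_association(calls_a, calls_b, self._identity_mapping(pos))
        assert res["all"].table == ((30, 10), (10, 50))
        assert res["all"].pvalue == pytest.approx(
            fisher_two_sided_oracle(30, 10, 10, 50), abs=1e-10
        )

    def test_unmapped_loci_counted_not_fatal(self):
        calls = [call_of(make_site(pos=p)) for p in (1, 2, 3)]
        mapping = self._identity_mapping([1, 2, 3, 99])
        res = conserved_locus_association(calls, calls, mapping)
        assert res["all"].n_unmapped == 1
        assert res["all"].n_loci == 3

    def test_null_calls_show_no_association(self):
        rng = np.random.default_rng(6)
        pos = np.arange(1, 2001)
        ca = [call_of(make_site(pos=int(p)), called=bool(rng.random() < 0.1)) for p in pos]
        cb = [call_of(make_site(pos=int(p)), called=bool(rng.random() < 0.1)) for p in pos]
        res = conserved_locus_association(ca, cb, self._identity_mapping(pos))
        assert res["all"].pvalue > 0.001  # no spurious association at fixed seed
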