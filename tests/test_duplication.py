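"""Tandem and intronless classification rules, and duplication enrichment."""

import numpy as np
import pytest

from upsdiverge.duplication import (
    DupConfig,
    DuplicationCall,
    GeneLocus,
    classify_intronless,
    classify_tandem,
    duplication_enrichment,
    loci_from_gff,
    read_gff3,
)


def _locus(locus_id, order_index, start, length=2000, subfam="FBX", introns=1):
    return GeneLocus(
        locus_id=locus_id, species="Aly", chromosome="chr1", start=start,
        end=start + length - 1, strand="+", order_index=order_index,
        intron_count=introns,
    )


def _tandem_flags(loci, subfam_map=None, **config_kwargs):
    subfam_map = subfam_map or {l.locus_id: "FBX" for l in loci}
    config = DupConfig(**config_kwargs) if config_kwargs else DupConfig()
    return {c.locus_id: c for c in classify_tandem(loci, subfam_map, config)}


class TestClassifyTandem:
    def test_pair_within_both_thresholds_is_tandem(self):
        # 5 intervening genes, 120 kb apart
        calls = _tandem_flags([_locus("a", 1, 1), _locus("b", 7, 120_000)])
        assert calls["a"].tandem and calls["b"].tandem
        assert calls["a"].tandem_partner == "b"

    def test_too_many_intervening_genes_fails_even_when_close(self):
        calls = _tandem_flags([_locus("a", 1, 1), _locus("b", 13, 120_000)])
        assert not calls["a"].tandem and not calls["b"].tandem

    def test_gene_count_boundary(self):
        # order-index difference 11 = exactly 10 intervening genes: tandem
        near = _tandem_flags([_locus("a", 1, 1), _locus("b", 12, 100_000)])
        assert near["a"].tandem
        far = _tandem_flags([_locus("a", 1, 1), _locus("b", 13, 100_000)])
        assert not far["a"].tandem

    def test_distance_boundary(self):
        a = _locus("a", 1, 1, length=2000)  # ends at 2000
        ok = _tandem_flags([a, _locus("b", 5, 302_000)])  # gap exactly 300 kb
        assert ok["a"].tandem
        fail = _tandem_flags([a, _locus("b", 5, 302_001)])
        assert not fail["a"].tandem

    def test_three_gene_array_all_tandem(self):
        loci = [_locus("a", 1, 1), _locus("b", 2, 30_001), _locus("c", 3, 60_001)]
        calls = _tandem_flags(loci)
        assert all(calls[x].tandem for x in "abc")

    def test_different_subfamilies_never_tandem(self):
        loci = [_locus("a", 1, 1), _locus("b", 2, 30_001)]
        calls = _tandem_flags(loci, subfam_map={"a": ("FBX", ("Kelch_1",)), "b": ("FBX", ())})
        assert not calls["a"].tandem

    def test_relation_is_symmetric(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(np.arange(1, 3_000_000, 25_000), size=30, replace=False))
        loci = [_locus(f"g{i}", i + 1, int(s)) for i, s in enumerate(starts)]
        subfam = {l.locus_id: ["FBX", "RING"][i % 2] for i, l in enumerate(loci)}
        calls = {c.locus_id: c for c in classify_tandem(loci, subfam)}
        for c in calls.values():
            if c.tandem:
                assert calls[c.tandem_partner].tandem

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(np.arange(1, 2_000_000, 10_000), size=40, replace=False))
        loci = [_locus(f"g{i}", i + 1, int(s)) for i, s in enumerate(starts)]

        def count(genes, kb):
            calls = _tandem_flags(loci, max_intervening_genes=genes, max_distance_bp=kb * 1000)
            return sum(c.tandem for c in calls.values())

        assert count(5, 100) <= count(10, 100) <= count(10, 300) <= count(20, 600)

    def test_missing_order_index_rejected(self):
        bad = _locus("a", 1, 1)
        bad.order_index = None
        with pytest.raises(ValueError, match="order_index"):
            classify_tandem([bad], {"a": "FBX"})

    def test_exact_recovery_on_lossless_truth(self, truth_lossless):
        subfam = truth_lossless.subfamily_of_locus()
        for sp in truth_lossless.species:
            calls = classify_tandem(truth_lossless.family_loci(sp), subfam)
            predicted = {c.locus_id for c in calls if c.tandem}
            assert predicted == truth_lossless.tandem_truth[sp]


GFF_TWO_ISOFORMS = """##gff-version 3
chr1\tsrc\tgene\t1\t5000\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t5000\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1.1
chr1\tsrc\tCDS\t1\t300\t.\t+\t0\tParent=g1.1
chr1\tsrc\tmRNA\t1\t5000\t.\t+\t.\tID=g1.2;Parent=g1
chr1\tsrc\texon\t1\t200\t.\t+\t.\tParent=g1.2
chr1\tsrc\texon\t1000\t1200\t.\t+\t.\tParent=g1.2
chr1\tsrc\texon\t2000\t2300\t.\t+\t.\tParent=g1.2
chr1\tsrc\tCDS\t1\t200\t.\t+\t0\tParent=g1.2
chr1\tsrc\tCDS\t1000\t1200\t.\t+\t0\tParent=g1.2
chr1\tsrc\tCDS\t2000\t2300\t.\t+\t0\tParent=g1.2
"""


class TestClassifyIntronless:
    def _gff(self, tmp_path, text):
        path = tmp_path / "m.gff3"
        path.write_text(text)
        return path

    def test_single_exon_model_is_intronless(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1.1\n"
            "chr1\tsrc\tCDS\t1\t300\t.\t+\t0\tParent=g1.1\n"
        )
        assert classify_intronless(self._gff(tmp_path, text)) == {"g1": True}

    def test_two_exon_model_is_not_intronless(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t900\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t900\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1.1\n"
            "chr1\tsrc\texon\t600\t900\t.\t+\t.\tParent=g1.1\n"
            "chr1\tsrc\tCDS\t1\t300\t.\t+\t0\tParent=g1.1\n"
            "chr1\tsrc\tCDS\t600\t900\t.\t+\t0\tParent=g1.1\n"
        )
        assert classify_intronless(self._gff(tmp_path, text)) == {"g1": False}

    def test_longest_cds_isoform_decides(self, tmp_path):
        # the 3-exon isoform has the longer CDS, so the locus keeps introns
        flags = classify_intronless(self._gff(tmp_path, GFF_TWO_ISOFORMS))
        assert flags == {"g1": False}

    def test_gene_without_exons_raises(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1\n"
        )
        with pytest.raises(ValueError, match="g1"):
            classify_intronless(self._gff(tmp_path, text))

    def test_recovery_of_planted_retrocopies(self, truth_lossless, tmp_path):
        from upsdiverge.synthetic_data import emit_files

        sp = "Aly"
        paths = emit_files(truth_lossless, tmp_path)
        flags = classify_intronless(paths[f"{sp}.gff3"])
        family_ids = {l.locus_id for l in truth_lossless.family_loci(sp)}
        predicted = {l for l, f in flags.items() if f and l in family_ids}
        assert predicted == truth_lossless.retro_truth(sp)


class TestDuplicationEnrichment:
    def _calls(self, n_pos, n_neg):
        out = [
            DuplicationCall(f"p{i}", tandem=True, intronless=False, tandem_partner=f"q{i}")
            for i in range(n_pos)
        ]
        out += [DuplicationCall(f"n{i}", tandem=False, intronless=False) for i in range(n_neg)]
        return out

    def test_extreme_table_matches_exact_hypergeometric(self):
        table, p = duplication_enrichment(self._calls(10, 0), self._calls(0, 10))
        assert table.tolist() == [[10, 0], [0, 10]]
        assert p == pytest.approx(2.0 / 184_756, rel=1e-9)

    def test_identical_proportions_give_p_one(self):
        _, p = duplication_enrichment(self._calls(5, 5), self._calls(5, 5))
        assert p == pytest.approx(1.0)

    def test_planted_rate_difference_detected(self):
        rng = np.random.default_rng(12)
        a_pos = int((rng.random(100) < 0.8).sum())
        b_pos = int((rng.random(100) < 0.2).sum())
        a = self._calls(a_pos, 100 - a_pos)
        b = self._calls(b_pos, 100 - b_pos)
        _, p = duplication_enrichment(a, b)
        assert p < 1e-5

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            duplication_enrichment([], self._calls(1, 1))
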