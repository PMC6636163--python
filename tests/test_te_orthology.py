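"""Framing, orthology calling and pairwise summaries."""

import dataclasses

import numpy as np
import pytest

import teretain as tr
from teretain import (
    AnnotatedGenome,
    GeneFeature,
    GenomicInterval,
    OrthologyThresholds,
    TECopy,
    call_orthology,
    frame_tes,
    orthologous_share_percent,
    run_pairwise,
    summarize_calls,
)
from teretain.gene_orthology import OrthologMap, OrthologPair
from teretain.te_orthology import OrthologyCall, OrthologySummary


def _rand(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), n))


def _gene(gene_id, sc, start, end):
    return GeneFeature(gene_id, GenomicInterval(sc, start, end),
                       [GenomicInterval(sc, start, end)])


def _te(te_id, sc, start, end, family="Gypsy_fam000", ident=80.0):
    return TECopy(te_id, GenomicInterval(sc, start, end), family, "Gypsy", ident)


def _identity_map(genes_a, genes_b):
    return {
        ga.gene_id: gb.gene_id for ga, gb in zip(genes_a, genes_b)
    }


class TestFraming:
    def _genomes(self):
        seq = _rand(20_000, 0)
        genes = [_gene("g1", "s", 1000, 2000), _gene("g2", "s", 8000, 9000),
                 _gene("g3", "s", 15_000, 16_000)]
        tes = [
            _te("framed_te", "s", 4000, 4400),
            _te("inserted_te", "s", 1200, 1400),
            _te("extremity_te", "s", 17_000, 17_300),
        ]
        g = AnnotatedGenome("A", {"s": seq}, genes, tes)
        h = AnnotatedGenome("B", {"s": seq}, [dataclasses.replace(x) for x in genes], [])
        return g, h

    def test_kinds_and_discards(self):
        g, h = self._genomes()
        gmap = _identity_map(g.genes, h.genes)
        frames, discarded = frame_tes(g, h, gmap)
        kinds = {f.te.te_id: f.kind for f in frames}
        assert kinds == {"framed_te": "framed", "inserted_te": "inserted"}
        assert [(c.te_id, c.discard_reason) for c in discarded] == [
            ("extremity_te", "scaffold_extremity")
        ]
        framed = next(f for f in frames if f.kind == "framed")
        assert framed.search_interval == GenomicInterval("s", 2000, 8000)
        assert framed.anchors == ("g1", "g2")

    def test_unmapped_host_gene_discards_inserted_te(self):
        g, h = self._genomes()
        gmap = _identity_map(g.genes, h.genes)
        del gmap["g1"]  # host of inserted_te no longer anchored
        frames, discarded = frame_tes(g, h, gmap)
        reasons = {c.te_id: c.discard_reason for c in discarded}
        assert reasons["inserted_te"] == "host_gene_unmapped"

    def test_long_counterpart_segment_discarded(self):
        g, h = self._genomes()
        gmap = _identity_map(g.genes, h.genes)
        frames, discarded = frame_tes(g, h, gmap, max_segment=5_000)
        reasons = {c.te_id: c.discard_reason for c in discarded}
        # both intergenic spans are 6 kb > 5 kb
        assert reasons["framed_te"] == "segment_too_long"

    def test_scaffold_without_mapped_genes(self):
        g, h = self._genomes()
        frames, discarded = frame_tes(g, h, {})
        assert frames == []
        assert {c.discard_reason for c in discarded} <= {
            "no_ortholog_scaffold", "host_gene_unmapped"
        }


class TestCalling:
    def _pair_with_te(self, family_b="Gypsy_fam000", keep_te_b=True):
        """A framed TE whose sequence survives verbatim between genome anchors."""
        rng = np.random.default_rng(1)
        te_seq = "".join(rng.choice(list("ACGT"), 400))
        left = _rand(1000, 2)
        gene1, gene2 = _rand(900, 3), _rand(900, 4)
        mid_a = _rand(800, 5) + te_seq + _rand(700, 6)
        mid_b = _rand(500, 7) + te_seq + _rand(900, 8)
        seq_a = left + gene1 + mid_a + gene2 + _rand(500, 9)
        seq_b = left + gene1 + mid_b + gene2 + _rand(500, 9)
        genes_a = [_gene("g1", "s", 1000, 1900), _gene("g2", "s", 1900 + len(mid_a), 2800 + len(mid_a))]
        genes_b = [_gene("h1", "s", 1000, 1900), _gene("h2", "s", 1900 + len(mid_b), 2800 + len(mid_b))]
        te_a = _te("qte", "s", 2700, 3100)
        tes_b = [_te("ste", "s", 2400, 2800, family=family_b)] if keep_te_b else []
        a = AnnotatedGenome("A", {"s": seq_a}, genes_a, [te_a])
        b = AnnotatedGenome("B", {"s": seq_b}, genes_b, tes_b)
        gmap = {"g1": "h1", "g2": "h2"}
        return a, b, gmap

    def test_same_family_hit_is_orthologous(self):
        a, b, gmap = self._pair_with_te()
        frames, _ = frame_tes(a, b, gmap)
        call = call_orthology(frames[0], a, b)
        assert call.status == "orthologous"
        assert call.matched_te_id == "ste"
        assert call.best_hit.e_value <= 1e-10 and call.best_hit.identity >= 80

    def test_different_family_hit_is_discarded_ambiguous(self):
        a, b, gmap = self._pair_with_te(family_b="Copia_fam001")
        frames, _ = frame_tes(a, b, gmap)
        call = call_orthology(frames[0], a, b)
        assert call.status == "discarded"
        assert call.discard_reason == "ambiguous_family"

    def test_relaxed_family_criterion_accepts_any_annotation(self):
        a, b, gmap = self._pair_with_te(family_b="Copia_fam001")
        frames, _ = frame_tes(a, b, gmap)
        call = call_orthology(
            frames[0], a, b, OrthologyThresholds(require_same_family=False)
        )
        assert call.status == "orthologous" and call.matched_te_id == "ste"

    def test_hit_without_annotation_is_non_orthologous(self):
        a, b, gmap = self._pair_with_te(keep_te_b=False)
        frames, _ = frame_tes(a, b, gmap)
        assert call_orthology(frames[0], a, b).status == "non_orthologous"

    def test_no_hit_is_non_orthologous(self):
        a, b, gmap = self._pair_with_te()
        # replace the counterpart segment with unrelated sequence
        s = b.sequences["s"]
        b.sequences["s"] = s[:1900] + _rand(len(s) - 1900 - 1400, 99) + s[-1400:]
        frames, _ = frame_tes(a, b, gmap)
        assert call_orthology(frames[0], a, b).status == "non_orthologous"

    def test_call_invariants(self):
        with pytest.raises(ValueError):
            OrthologyCall("t", "orthologous", "scaffold_extremity")
        with pytest.raises(ValueError):
            OrthologyCall("t", "non_orthologous", matched_te_id="x")


class TestPairwise:
    def test_self_comparison_calls_every_interrogated_te_orthologous(self, small_sim):
        genome = small_sim["genome_a"]
        twin = AnnotatedGenome(
            "twin", dict(genome.sequences),
            [dataclasses.replace(g) for g in genome.genes],
            [dataclasses.replace(t) for t in genome.tes],
        )
        m = OrthologMap(
            [OrthologPair(g.gene_id, g.gene_id, 100.0, 100.0, 100.0, 1.0)
             for g in genome.genes]
        )
        res = run_pairwise(genome, twin, m)
        for calls in (res.calls_a, res.calls_b):
            for c in calls:
                assert c.status in ("orthologous", "discarded")
                if c.status == "orthologous":
                    assert c.matched_te_id == c.te_id

    def test_partition_reconciles_with_te_total(self, small_pairwise):
        res = small_pairwise["result"]
        for calls, genome in (
            (res.calls_a, small_pairwise["genome_a"]),
            (res.calls_b, small_pairwise["genome_b"]),
        ):
            assert len(calls) == len(genome.tes)
            s = summarize_calls(calls)
            assert s.interrogated + s.discarded == len(genome.tes)

    def test_threshold_monotonicity(self, small_pairwise):
        a, b = small_pairwise["genome_a"], small_pairwise["genome_b"]
        m = small_pairwise["map"]
        base = summarize_calls(
            run_pairwise(a, b, m, OrthologyThresholds()).calls_a
        ).total_orthologous
        tighter = summarize_calls(
            run_pairwise(
                a, b, m, OrthologyThresholds(e_max=1e-30, min_identity=95.0)
            ).calls_a
        ).total_orthologous
        assert tighter <= base

    def test_max_segment_robustness(self, small_pairwise):
        """Call sets barely move across 50/70/100 kb caps (Jaccard >= 0.9)."""
        a, b = small_pairwise["genome_a"], small_pairwise["genome_b"]
        m = small_pairwise["map"]
        orth_sets = []
        for cap in (50_000, 70_000, 100_000):
            calls = run_pairwise(
                a, b, m, OrthologyThresholds(max_segment=cap)
            ).calls_a
            orth_sets.append({c.te_id for c in calls if c.status == "orthologous"})
        for other in orth_sets[1:]:
            inter = len(orth_sets[0] & other)
            union = len(orth_sets[0] | other)
            assert inter / union >= 0.9

    def test_truth_recovery_on_simulated_pair(self, small_pairwise):
        res = small_pairwise["result"]
        truth = small_pairwise["truth"]
        for calls, d in ((res.calls_a, "a"), (res.calls_b, "b")):
            ev = tr.evaluate_against_truth(calls, truth, d)
            assert ev.precision >= 0.95 and ev.recall >= 0.95


class TestSummaries:
    def test_table_totals_from_components(self):
        s = OrthologySummary(
            old_orthologous=4_642, young_orthologous=631,
            old_non_orthologous=31_471, young_non_orthologous=19_771,
        )
        assert s.total_orthologous == 5_273
        assert s.total_non_orthologous == 51_242

    @pytest.mark.parametrize(
        "n_orth,n_total,expected",
        [(5_273, 25_990, 20.3), (5_273, 35_798, 14.7)],
    )
    def test_orthologous_share(self, n_orth, n_total, expected):
        assert orthologous_share_percent(n_orth, n_total) == expected
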