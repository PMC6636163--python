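"""Statistical machinery for the retention-factor contrasts."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import teretain as tr
from teretain import (
    GenomicInterval,
    SiRNAProfile,
    TECopy,
    chi2_2x2,
    compare_distances,
    compare_lengths,
    compare_locations,
    compare_superfamilies,
    methylation_group_test,
    nei_gojobori,
    percent_change,
    significance_code,
    sirna_active,
    te_methylation_percent,
    tpm_normalize,
)
from teretain.retention import _nemenyi


def _te(te_id, sf="Gypsy", start=0, end=100):
    return TECopy(te_id, GenomicInterval("s", start, end), f"{sf}_fam000", sf, 80.0)


class TestChi2:
    def test_no_association_gives_zero(self):
        stat, p = chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_known_table(self):
        stat, p = chi2_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / 30**4)
        assert stat == pytest.approx(6.667, abs=1e-3)
        assert p == pytest.approx(0.0098, abs=2e-4)
        assert significance_code(p) == "**"

    def test_closed_form_equals_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(1, 200, size=(2, 2))
            stat, p = chi2_2x2(t)
            ref, ref_p, _, _ = stats.chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref, rel=1e-9)
            assert p == pytest.approx(ref_p, rel=1e-9)

    def test_yates_correction_reduces_statistic(self):
        plain, _ = chi2_2x2([[12, 5], [4, 13]])
        corrected, _ = chi2_2x2([[12, 5], [4, 13]], yates=True)
        assert corrected < plain


class TestSignificanceCodes:
    @pytest.mark.parametrize(
        "p,code",
        [(1e-5, "***"), (0.0005, "***"), (0.005, "**"), (0.03, "*"),
         (0.07, "."), (0.1, "."), (0.2, "NS"), (0.9, "NS")],
    )
    def test_cut_points(self, p, code):
        assert significance_code(p) == code


class TestLengthsAndDistances:
    def test_identical_groups_p_one(self):
        rep = compare_lengths([100, 200, 300], [100, 200, 300])
        assert rep.p_value == pytest.approx(1.0)

    def test_disjoint_ranks_u_zero(self):
        rep = compare_lengths([1, 2, 3], [4, 5, 6])
        assert rep.statistic == 0.0

    def test_printed_means_reproduce_percent_shorter(self):
        # percent difference computed straight from the group means
        assert percent_change(401.6, 307.3) == -23.5
        rep = compare_lengths([307.3, 307.3], [401.6, 401.6])
        assert rep.extra["percent_shorter"] == 23.5

    def test_printed_means_reproduce_percent_farther(self):
        assert percent_change(1768.8, 2303.3) == 30.2
        rep = compare_distances([1768.8, 1768.8], [2303.3, 2303.3])
        assert rep.extra["percent_farther"] == 30.2

    def test_distance_dependent_deletion_orders_means(self):
        rng = np.random.default_rng(1)
        dist = rng.exponential(2000, 2000)
        keep = rng.random(2000) > np.minimum(1.0, dist / 4000)  # far -> deleted
        rep = compare_distances(dist[keep], dist[~keep])
        assert rep.groups["orthologous"]["mean"] < rep.groups["non_orthologous"]["mean"]
        assert rep.p_value < 0.001

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_lengths([1.0], [2.0, 3.0])


class TestCategoricalFactors:
    def test_balanced_superfamilies_not_significant(self):
        orth = [_te(f"o{i}", "Gypsy") for i in range(10)] + [
            _te(f"o{i+10}", "Copia") for i in range(10)
        ]
        non = [_te(f"n{i}", "Gypsy") for i in range(10)] + [
            _te(f"n{i+10}", "Copia") for i in range(10)
        ]
        reports = compare_superfamilies(orth, non)
        assert all(r.statistic == 0.0 and r.code == "NS" for r in reports.values())

    def test_sheltered_superfamily_flagged(self):
        rng = np.random.default_rng(2)
        orth, non = [], []
        for i in range(2000):
            sf = "Helitron" if rng.random() < 0.15 else "Gypsy"
            retained = rng.random() < (0.8 if sf == "Helitron" else 0.5)
            (orth if retained else non).append(_te(f"t{i}", sf))
        rep = compare_superfamilies(orth, non)["Helitron"]
        assert rep.p_value < 0.001
        assert (
            rep.groups["orthologous"]["fraction"]
            > rep.groups["non_orthologous"]["fraction"]
        )

    def test_mixed_age_input_refused_unless_forced(self):
        old = [_te(f"o{i}") for i in range(5)]
        young = [dataclasses.replace(_te(f"y{i}"), identity_to_consensus=96.0)
                 for i in range(5)]
        with pytest.raises(ValueError, match="young TE"):
            compare_superfamilies(old, young)
        assert compare_superfamilies(old, young, allow_mixed_ages=True)

    def test_all_intergenic_not_significant(self):
        rep1, rep2 = compare_locations(["intergenic"] * 10, ["intergenic"] * 12)
        assert rep1.statistic == 0.0 and rep1.code == "NS"
        assert rep2.statistic == 0.0

    def test_equal_three_way_distributions_give_zero(self):
        locs = ["genic_cds"] * 5 + ["genic_noncds"] * 5 + ["intergenic"] * 10
        _, rep2 = compare_locations(locs, list(locs))
        assert rep2.statistic == pytest.approx(0.0)


class TestSiRNA:
    @pytest.mark.parametrize(
        "rpm,cov,active",
        [(6, 0.2, True), (6, 0.05, False), (4, 0.5, False), (5, 0.10, True)],
    )
    def test_activity_rule(self, rpm, cov, active):
        assert sirna_active(SiRNAProfile("t", rpm, cov)) is active

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            SiRNAProfile("t", -1.0, 0.5)


class TestMethylation:
    def _matrix(self, rates):
        return pd.DataFrame(
            {
                "scaffold": "s",
                "position": np.arange(len(rates)),
                "context": "CG",
                "shoot": [r[0] for r in rates],
                "root": [r[1] for r in rates],
                "cold4C": [r[2] for r in rates],
                "warm23C": [r[3] for r in rates],
            }
        )

    def test_single_condition_over_threshold_counts(self):
        te = _te("t", start=0, end=10)
        m = self._matrix([(0.25, 0.1, 0.0, 0.0)])
        assert te_methylation_percent(te, m) == 100.0

    def test_three_of_ten_sites(self):
        rates = [(0.5, 0, 0, 0)] * 3 + [(0.05, 0.1, 0.0, 0.1)] * 7
        te = _te("t", start=0, end=10)
        assert te_methylation_percent(te, self._matrix(rates)) == 30.0

    def test_no_covered_site_is_missing(self):
        te = _te("t", start=1000, end=1100)
        assert te_methylation_percent(te, self._matrix([(0.5, 0, 0, 0)])) is None

    def test_identical_groups_h_near_zero(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        rep = methylation_group_test(g)
        assert rep.statistic == pytest.approx(0.0, abs=1e-9)
        assert rep.p_value > 0.99

    def test_shifted_group_detected_and_localized(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": list(rng.normal(0, 1, 200)) for i in range(3)}
        groups["shifted"] = list(rng.normal(1.0, 1, 200))
        rep = methylation_group_test(groups)
        assert rep.p_value < 0.001
        for (a, b), p in rep.pairwise.items():
            if "shifted" in (a, b):
                assert p < 0.01
            else:
                assert p > 0.05

    def test_two_groups_agree_with_mannwhitney(self):
        rng = np.random.default_rng(4)
        x = list(rng.normal(0, 1, 80))
        y = list(rng.normal(0.4, 1, 80))
        rep = methylation_group_test({"x": x, "y": y})
        mw = stats.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic", use_continuity=False).pvalue
        assert rep.p_value == pytest.approx(mw, rel=0.1)

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            rep = methylation_group_test({"a": [1, 2, 3], "b": [2, 3, 4], "c": []})
        assert set(rep.groups) == {"a", "b"}


class TestTPM:
    def test_closed_form(self):
        tpm = tpm_normalize([10, 10], [1000, 2000])
        assert tpm == pytest.approx([666666.666667, 333333.333333])
        assert tpm.sum() == pytest.approx(1e6)

    def test_single_transcript(self):
        assert tpm_normalize([7], [500])[0] == pytest.approx(1e6)

    def test_permutation_equivariance(self):
        counts, lengths = [5, 9, 2], [100, 300, 250]
        perm = [2, 0, 1]
        direct = tpm_normalize(counts, lengths)[perm]
        permuted = tpm_normalize(np.array(counts)[perm], np.array(lengths)[perm])
        assert direct == pytest.approx(permuted)

    def test_all_zero_counts_warn(self):
        with pytest.warns(UserWarning, match="zero"):
            assert tpm_normalize([0, 0], [100, 100]).tolist() == [0.0, 0.0]


class TestNeiGojobori:
    def test_identical_pair_excluded(self):
        ka, ks, ratio = nei_gojobori("ATGGCTAAG", "ATGGCTAAG")
        assert ka == 0.0 and ks == 0.0 and ratio is None

    def test_single_synonymous_change_hand_oracle(self):
        # GGA->GGG (Gly->Gly), one synonymous difference in a 6-codon frame.
        # Hand-counted NG86 synonymous sites per codon (third-position
        # changes only, stop mutations non-synonymous):
        #   ATG 0, GGA 1, AAG 1/3, CCT 1, TTC 1/3, GAT 1/3  -> S = 3, N = 15
        # and GGG also has 1, so both sequences give S = 3.
        a = "ATG" + "GGA" + "AAG" + "CCT" + "TTC" + "GAT"
        b = "ATG" + "GGG" + "AAG" + "CCT" + "TTC" + "GAT"
        ka, ks, ratio = nei_gojobori(a, b)
        assert ka == 0.0
        p_s = 1.0 / 3.0
        assert ks == pytest.approx(-0.75 * math.log(1 - 4 * p_s / 3))
        assert ratio == 0.0

    def test_single_nonsynonymous_change(self):
        # GCT->TCT (Ala->Ser): nonsynonymous only
        ka, ks, ratio = nei_gojobori("ATGGCTAAA", "ATGTCTAAA")
        assert ks == 0.0 and ka > 0.0 and ratio is None

    def test_purifying_regime_ratio_below_one(self):
        rng = np.random.default_rng(6)
        codons = [c for c in ("GCT", "GGA", "CTT", "CCT", "TCT", "ACT")]
        a = "ATG" + "".join(rng.choice(codons, 200))
        b = list(a)
        # third positions of fourfold codons mutate freely: mostly synonymous
        for i in range(5, len(b), 6):
            if b[i - 2 : i + 1] != list("ATG") and rng.random() < 0.5:
                b[i] = rng.choice(list("ACGT"))
        ka, ks, ratio = nei_gojobori(a, "".join(b))
        assert ratio is not None and ratio < 0.5


class TestExpressionComparison:
    def _host_setup(self, n, counts, statuses):
        """n genes on one scaffold, each hosting one old TE with given status."""
        from teretain.te_orthology import OrthologyCall

        seq = "A" * (n * 50 + 100)
        genes, tes, calls = [], [], []
        for i in range(n):
            s = i * 50
            iv = GenomicInterval("s", s, s + 30)
            genes.append(tr.GeneFeature(f"g{i}", iv, [iv]))
            tes.append(TECopy(f"t{i}", GenomicInterval("s", s + 5, s + 15),
                              "Gypsy_fam000", "Gypsy", 80.0))
            calls.append(OrthologyCall(f"t{i}", statuses[i]))
        genome = tr.AnnotatedGenome("x", {"s": seq}, genes, tes)
        expr = pd.DataFrame({
            "transcript_id": [f"g{i}" for i in range(n)],
            "length": 30,
            "count": counts,
        })
        return calls, expr, genome

    def test_identical_distributions_not_significant(self):
        counts = list(range(10, 50)) * 2
        statuses = ["orthologous"] * 40 + ["non_orthologous"] * 40
        calls, expr, genome = self._host_setup(80, counts[:80], statuses)
        reports = tr.retention.expression_comparison(calls, expr, genome)
        assert reports["host_gene"].p_value > 0.5

    def test_expression_dependent_deletion_detected(self):
        rng = np.random.default_rng(9)
        n = 500
        counts = rng.lognormal(3, 1, n).astype(int) + 1
        # deletion odds increase with host expression
        p_del = np.minimum(0.9, counts / counts.max())
        statuses = ["non_orthologous" if rng.random() < p else "orthologous"
                    for p in p_del]
        calls, expr, genome = self._host_setup(n, counts, statuses)
        reports = tr.retention.expression_comparison(calls, expr, genome)
        rep = reports["host_gene"]
        assert (rep.groups["orthologous"]["mean"]
                < rep.groups["non_orthologous"]["mean"])
        assert rep.p_value < 0.05

    def test_empty_intergenic_group_skipped_with_warning(self):
        calls, expr, genome = self._host_setup(
            10, list(range(10, 20)), ["orthologous"] * 5 + ["non_orthologous"] * 5
        )
        with pytest.warns(UserWarning, match="nearest_gene"):
            reports = tr.retention.expression_comparison(calls, expr, genome)
        assert "nearest_gene" not in reports and "host_gene" in reports


class TestEssentialityReport:
    def test_proxies_on_simulated_pair(self, small_pairwise):
        genome_a = small_pairwise["genome_a"]
        lof = {g.gene_id for g in genome_a.genes[::2]}
        reports = tr.essentiality_report(
            genome_a, small_pairwise["genome_b"], small_pairwise["map"],
            small_pairwise["result"].calls_a, loss_of_function_genes=lof,
        )
        # independently drawn genes: every gene single copy in every group
        for key in [k for k in reports if k.startswith("single_copy")]:
            for grp in reports[key].groups.values():
                assert grp["single_copy_fraction"] == 1.0
        # orthologs diverged ~2% under (near-)neutral substitution: ratios
        # defined, scattered around 1 (the ratio of noisy estimates is
        # upward-biased at this divergence, so allow a generous band)
        kaks = reports["kaks"]
        assert kaks.groups["all"]["n"] >= 10
        assert 0.4 < kaks.groups["all"]["mean"] < 2.5
        assert kaks.pairwise  # Nemenyi pairwise p-values present
        assert kaks.p_value > 0.001  # no artefactual group difference
        # LoF fractions reflect the constructed half/half split
        lof_all = reports["lof:with_orthologous_te"].groups["all"]["lof_fraction"]
        assert lof_all == pytest.approx(0.5, abs=0.05)


class TestFamilySizes:
    def test_unrelated_genes_are_single_copy(self, small_sim):
        from teretain import gene_family_sizes

        genome = small_sim["genome_a"]
        sizes = gene_family_sizes(genome)
        # the simulator draws every gene independently: no paralogs
        assert sizes and all(v == 1 for v in sizes.values())

    def test_duplicated_gene_forms_a_family(self):
        rng = np.random.default_rng(8)
        seq_core = "ATG" + "".join(rng.choice(list("ACGT"), 600))
        other = "ATG" + "".join(rng.choice(list("ACGT"), 600))
        genome_seq = seq_core + "TTTT" + seq_core + "TTTT" + other
        genes = []
        offset = 0
        for i, s in enumerate([seq_core, seq_core, other]):
            iv = GenomicInterval("s", offset, offset + len(s))
            genes.append(tr.GeneFeature(f"g{i}", iv, [iv]))
            offset += len(s) + 4
        genome = tr.AnnotatedGenome("x", {"s": genome_seq}, genes, [])
        sizes = tr.gene_family_sizes(genome)
        assert sizes["g0"] == sizes["g1"] == 2 and sizes["g2"] == 1
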