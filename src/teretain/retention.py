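"""Factor analyses contrasting orthologous vs non-orthologous old TEs.

Every comparison follows the same template: restrict to old copies (the fate
of young copies cannot be polarized), split them by orthology status, and
test the factor with the appropriate nonparametric machinery - chi-squared
(no continuity correction) for categorical factors, Mann-Whitney for scalar
ones, Kruskal-Wallis with a rank-based Tukey-Kramer (Nemenyi) post-hoc for
the four-group methylation and Ka/Ks contrasts.  Significance codes:
'***' p<0.001, '**' p<0.01, '*' p<0.05, '.' p<=0.1, 'NS' otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from ._align import AlignParams, local_align
from .formats import AnnotatedGenome, GeneIndex, TECopy, classify_te_location, nearest_gene_distance
from .gene_orthology import OrthologMap, TranslationError

__all__ = [
    "FactorReport",
    "SiRNAProfile",
    "significance_code",
    "chi2_2x2",
    "percent_change",
    "compare_superfamilies",
    "compare_lengths",
    "compare_locations",
    "compare_distances",
    "sirna_active",
    "te_methylation_percent",
    "methylation_group_test",
    "tpm_normalize",
    "expression_comparison",
    "nei_gojobori",
    "gene_family_sizes",
    "essentiality_report",
]


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p <= 0.1:
        return "."
    return "NS"


@dataclass
class FactorReport:
    factor: str
    test: str
    statistic: float
    p_value: float
    df: int | None = None
    groups: dict = field(default_factory=dict)
    table: np.ndarray | None = None
    pairwise: dict | None = None
    extra: dict = field(default_factory=dict)

    @property
    def code(self) -> str:
        return significance_code(self.p_value)


@dataclass(frozen=True)
class SiRNAProfile:
    te_id: str
    reads_per_million: float
    covered_fraction: float

    def __post_init__(self) -> None:
        if self.reads_per_million < 0 or not (0.0 <= self.covered_fraction <= 1.0):
            raise ValueError(f"invalid siRNA profile for {self.te_id}")


# ---------------------------------------------------------------------------
# Basic statistical machinery
# ---------------------------------------------------------------------------

def chi2_2x2(table, yates: bool = False) -> tuple[float, float]:
    """1-df chi-squared on a 2x2 table via the closed form N(ad-bc)^2/(r1 r2 c1 c2)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi2_2x2 expects a 2x2 table")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / denom
    return float(stat), float(stats.chi2.sf(stat, 1))


def percent_change(reference: float, value: float) -> float:
    """(value - reference) / reference in percent, to one decimal."""
    if reference == 0:
        raise ValueError("reference mean is zero")
    return round(100.0 * (value - reference) / reference, 1)


def _mannwhitney(x, y) -> tuple[float, float]:
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(min(1.0, res.pvalue))


# ---------------------------------------------------------------------------
# Categorical factors
# ---------------------------------------------------------------------------

def compare_superfamilies(
    orthologous: list[TECopy],
    non_orthologous: list[TECopy],
    age_threshold: float = 90.0,
    allow_mixed_ages: bool = False,
) -> dict[str, FactorReport]:
    """Per superfamily, a 2x2 (in-superfamily x orthology) chi-squared test.

    Factor contrasts are only meaningful for old copies (whose absence from
    one genome is interpretable as deletion); mixed-age input is refused
    unless ``allow_mixed_ages`` is set.
    """
    if not orthologous or not non_orthologous:
        raise ValueError("both groups must be non-empty")
    if not allow_mixed_ages:
        young = [
            t.te_id for t in orthologous + non_orthologous
            if t.identity_to_consensus is not None
            and t.identity_to_consensus >= age_threshold
        ]
        if young:
            raise ValueError(
                f"{len(young)} young TE(s) in a factor contrast (e.g. "
                f"{young[0]}); restrict to old copies or pass allow_mixed_ages"
            )
    n_o, n_n = len(orthologous), len(non_orthologous)
    reports = {}
    seen = sorted({t.superfamily for t in orthologous + non_orthologous})
    for sf in seen:
        a = sum(t.superfamily == sf for t in orthologous)
        c = sum(t.superfamily == sf for t in non_orthologous)
        table = np.array([[a, n_o - a], [c, n_n - c]], dtype=float)
        stat, p = chi2_2x2(table)
        reports[sf] = FactorReport(
            factor=f"superfamily:{sf}",
            test="chi2_1df",
            statistic=stat,
            p_value=p,
            df=1,
            table=table,
            groups={
                "orthologous": {"n": n_o, "fraction": a / n_o},
                "non_orthologous": {"n": n_n, "fraction": c / n_n},
            },
        )
    return reports


def compare_lengths(lengths_orth, lengths_non) -> FactorReport:
    """TE length contrast: means/medians, percent-shorter, Mann-Whitney."""
    x = np.asarray(lengths_orth, dtype=float)
    y = np.asarray(lengths_non, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    u, p = _mannwhitney(x, y)
    return FactorReport(
        factor="length",
        test="mannwhitney",
        statistic=u,
        p_value=p,
        groups={
            "orthologous": {"n": x.size, "mean": float(x.mean()), "median": float(np.median(x))},
            "non_orthologous": {"n": y.size, "mean": float(y.mean()), "median": float(np.median(y))},
        },
        extra={
            # shorter relative to the copies that were deleted (the larger mean)
            "percent_shorter": percent_change(float(y.mean()), float(x.mean())) * -1.0
        },
    )


def compare_locations(
    loc_orth: list[str], loc_non: list[str], genome: AnnotatedGenome | None = None
) -> tuple[FactorReport, FactorReport]:
    """Genic-vs-not (1 df) and CDS/non-CDS/intergenic (2 df) chi-squared tests."""
    if not loc_orth or not loc_non:
        raise ValueError("both groups must be non-empty")

    def genic(v):
        return sum(x != "intergenic" for x in v)

    a, c = genic(loc_orth), genic(loc_non)
    t1 = np.array(
        [[a, len(loc_orth) - a], [c, len(loc_non) - c]], dtype=float
    )
    stat1, p1 = chi2_2x2(t1)
    classes = ["genic_cds", "genic_noncds", "intergenic"]
    t2 = np.array(
        [
            [sum(x == cl for x in loc_orth) for cl in classes],
            [sum(x == cl for x in loc_non) for cl in classes],
        ],
        dtype=float,
    )
    sub = t2[:, t2.sum(axis=0) > 0]  # drop unobserved classes
    if sub.shape[1] < 2:
        stat2, p2, df2 = 0.0, 1.0, 0
    else:
        stat2, p2, df2, _ = stats.chi2_contingency(sub, correction=False)
    genic_baseline = None
    if genome is not None:
        genic_bp = sum(g.interval.length for g in genome.genes)
        total_bp = sum(len(s) for s in genome.sequences.values())
        genic_baseline = genic_bp / total_bp
    rep1 = FactorReport(
        factor="location_genic",
        test="chi2_1df",
        statistic=float(stat1),
        p_value=float(p1),
        df=1,
        table=t1,
        groups={
            "orthologous": {"n": len(loc_orth), "genic_fraction": a / len(loc_orth)},
            "non_orthologous": {"n": len(loc_non), "genic_fraction": c / len(loc_non)},
        },
        extra={"genome_genic_fraction": genic_baseline},
    )
    rep2 = FactorReport(
        factor="location_3way",
        test="chi2_2df",
        statistic=float(stat2),
        p_value=float(p2),
        df=int(df2),
        table=t2,
    )
    return rep1, rep2


def compare_distances(dist_orth, dist_non) -> FactorReport:
    """Distance-to-nearest-gene contrast for intergenic TEs."""
    x = np.asarray([d for d in dist_orth if d is not None], dtype=float)
    y = np.asarray([d for d in dist_non if d is not None], dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 distances")
    u, p = _mannwhitney(x, y)
    return FactorReport(
        factor="gene_distance",
        test="mannwhitney",
        statistic=u,
        p_value=p,
        groups={
            "orthologous": {"n": x.size, "mean": float(x.mean())},
            "non_orthologous": {"n": y.size, "mean": float(y.mean())},
        },
        # farther relative to the orthologous mean
        extra={"percent_farther": percent_change(float(x.mean()), float(y.mean()))},
    )


# ---------------------------------------------------------------------------
# siRNA and methylation
# ---------------------------------------------------------------------------

def sirna_active(
    profile: SiRNAProfile, min_rpm: float = 5.0, min_cov: float = 0.10
) -> bool:
    """Substantial siRNA production: rpm and length-coverage cut-offs both met."""
    return profile.reads_per_million >= min_rpm and profile.covered_fraction >= min_cov


def te_methylation_percent(
    te: TECopy,
    matrix: pd.DataFrame,
    site_threshold: float = 0.20,
) -> float | None:
    """Percent of covered cytosines in the TE that are methylated.

    A site counts as methylated when its rate is >= ``site_threshold`` in at
    least one of the condition columns.  Returns None when no covered site
    falls inside the TE.
    """
    condition_cols = [
        c for c in matrix.columns if c not in ("scaffold", "position", "context")
    ]
    sel = matrix[
        (matrix["scaffold"] == te.interval.scaffold_id)
        & (matrix["position"] >= te.interval.start)
        & (matrix["position"] < te.interval.end)
    ]
    if sel.empty:
        return None
    methylated = (sel[condition_cols].to_numpy(dtype=float) >= site_threshold).any(axis=1)
    return round(100.0 * float(methylated.mean()), 4)


def _nemenyi(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Rank-based Tukey-Kramer (Nemenyi) pairwise p-values."""
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_rank = {}
    pos = 0
    for g in names:
        n = groups[g].size
        mean_rank[g] = ranks[pos : pos + n].mean()
        pos += n
    k = len(names)
    out = {}
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = groups[g1].size, groups[g2].size
        se = math.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / n1 + 1.0 / n2))
        z = abs(mean_rank[g1] - mean_rank[g2]) / se
        p = float(stats.studentized_range.sf(z * math.sqrt(2.0), k, np.inf))
        out[(g1, g2)] = min(1.0, p)
    return out


def methylation_group_test(groups: dict[str, list[float]]) -> FactorReport:
    """Kruskal-Wallis over >= 2 groups with Nemenyi pairwise comparisons."""
    clean = {
        g: np.asarray([v for v in vals if v is not None], dtype=float)
        for g, vals in groups.items()
    }
    empty = [g for g, v in clean.items() if v.size == 0]
    for g in empty:
        warnings.warn(f"group {g!r} is empty; skipped from the comparison")
        del clean[g]
    if len(clean) < 2:
        raise ValueError("need at least 2 non-empty groups")
    arrays = [clean[g] for g in sorted(clean)]
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0
    return FactorReport(
        factor="methylation_groups",
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        df=len(clean) - 1,
        groups={
            g: {"n": clean[g].size, "mean": float(clean[g].mean()),
                "median": float(np.median(clean[g]))}
            for g in sorted(clean)
        },
        pairwise=_nemenyi(clean),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def tpm_normalize(counts, lengths) -> np.ndarray:
    """Transcripts-per-million from raw counts and transcript lengths in bp."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPM set to zero")
        return np.zeros_like(rate)
    return rate / total * 1e6


def expression_comparison(
    calls: list,
    expression: pd.DataFrame,
    genome: AnnotatedGenome,
    transcript_to_gene: dict[str, str] | None = None,
) -> dict[str, FactorReport]:
    """Host-gene (inserted TEs) and nearest-gene (intergenic TEs) expression.

    ``expression`` needs columns transcript_id, length, count; transcripts map
    to genes through ``transcript_to_gene`` (identity by default, standing in
    for the stringent sequence-match rule used with a real transcriptome).
    """
    mapping = transcript_to_gene or {t: t for t in expression["transcript_id"]}
    expr = expression.copy()
    expr["gene_id"] = expr["transcript_id"].map(mapping)
    unmapped = int(expr["gene_id"].isna().sum())
    if unmapped:
        warnings.warn(f"{unmapped} transcript(s) had no gene match; dropped")
        expr = expr.dropna(subset=["gene_id"])
    expr["tpm"] = tpm_normalize(expr["count"], expr["length"])
    tpm = expr.groupby("gene_id")["tpm"].sum().to_dict()

    index = GeneIndex(genome.genes)
    status = {c.te_id: c.status for c in calls}
    te_by_id = {t.te_id: t for t in genome.tes}
    host_groups: dict[str, list[float]] = {"orthologous": [], "non_orthologous": []}
    near_groups: dict[str, list[float]] = {"orthologous": [], "non_orthologous": []}
    for te_id, st in status.items():
        if st not in ("orthologous", "non_orthologous") or te_id not in te_by_id:
            continue
        te = te_by_id[te_id]
        overlapping = index.overlapping_genes(te.interval)
        if overlapping:
            vals = [tpm[g.gene_id] for g in overlapping if g.gene_id in tpm]
            if vals:
                host_groups[st].append(float(np.mean(vals)))
        else:
            near = None
            best = None
            for g in genome.genes:
                if g.interval.scaffold_id != te.interval.scaffold_id:
                    continue
                gap = te.interval.gap_to(g.interval)
                if best is None or gap < best:
                    best, near = gap, g
            if near is not None and near.gene_id in tpm:
                near_groups[st].append(tpm[near.gene_id])

    out = {}
    for name, grp in (("host_gene", host_groups), ("nearest_gene", near_groups)):
        x, y = grp["orthologous"], grp["non_orthologous"]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"expression contrast {name!r} skipped: a group is empty/too small")
            continue
        u, p = _mannwhitney(x, y)
        out[name] = FactorReport(
            factor=f"expression_{name}",
            test="mannwhitney",
            statistic=u,
            p_value=p,
            groups={
                "orthologous": {"n": len(x), "mean": float(np.mean(x))},
                "non_orthologous": {"n": len(y), "mean": float(np.mean(y))},
            },
        )
    return out


# ---------------------------------------------------------------------------
# Essentiality proxies
# ---------------------------------------------------------------------------

_CODON_AA: dict[str, str] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _CODON_AA[_codon] = str(Seq(_codon).translate())


def _codon_syn_sites(codon: str) -> float:
    aa = _CODON_AA[codon]
    syn = 0
    for pos in range(3):
        for alt in "TCAG":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_AA[mutant] == aa and _CODON_AA[mutant] != "*":
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over mutational pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_AA[nxt] == "*" and nxt != c2:
                through_stop = True
            if _CODON_AA[nxt] == _CODON_AA[cur] and _CODON_AA[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    usable = [p for p in paths if not p[2]] or paths
    sd = float(np.mean([p[0] for p in usable]))
    nd = float(np.mean([p[1] for p in usable]))
    return sd, nd


def _paired_codons(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    if len(cds_a) == len(cds_b):
        a, b = cds_a, cds_b
    else:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        alignment = aligner.align(cds_a, cds_b)[0]
        sa, sb = str(alignment[0]), str(alignment[1])
        # keep gap-free columns; frame follows sequence a
        a_chars = [ca for ca, cb in zip(sa, sb) if ca != "-" and cb != "-"]
        b_chars = [cb for ca, cb in zip(sa, sb) if ca != "-" and cb != "-"]
        a, b = "".join(a_chars), "".join(b_chars)
    pairs = []
    for i in range(0, min(len(a), len(b)) - 2, 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "*" in (_CODON_AA.get(ca, "*"), _CODON_AA.get(cb, "*")):
            continue
        pairs.append((ca, cb))
    return pairs


def nei_gojobori(cds_a: str, cds_b: str) -> tuple[float | None, float | None, float | None]:
    """Nei-Gojobori (1986) counting Ka, Ks and their ratio for a CDS pair.

    Proportions are Jukes-Cantor corrected; returns (ka, ks, ratio) with the
    ratio None when Ks is zero or undefined (excluded from group summaries).
    """
    pairs = _paired_codons(cds_a.upper(), cds_b.upper())
    if not pairs:
        return None, None, None
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in pairs:
        s_a, s_b = _codon_syn_sites(ca), _codon_syn_sites(cb)
        s_sites += (s_a + s_b) / 2.0
        n_sites += 3.0 - (s_a + s_b) / 2.0
        if ca != cb:
            dsd, dnd = _pathway_counts(ca, cb)
            sd += dsd
            nd += dnd

    def jc(p: float) -> float | None:
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ks = jc(sd / s_sites) if s_sites > 0 else None
    ka = jc(nd / n_sites) if n_sites > 0 else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return ka, ks, ratio


def gene_family_sizes(
    genome: AnnotatedGenome,
    e_max: float = 1e-30,
    min_query_coverage: float = 50.0,
    params: AlignParams | None = None,
) -> dict[str, int]:
    """Family size per gene = size of its connected component in the
    all-vs-all CDS hit graph (hits filtered on E-value and query coverage).

    A gene with no passing non-self hit has family size 1 (single copy).
    """
    p = params or AlignParams(k=13)
    cds = {}
    for g in genome.genes:
        seq = "".join(genome.sequence_of(c) for c in g.cds_intervals)
        if seq:
            cds[g.gene_id] = seq
    graph = nx.Graph()
    graph.add_nodes_from(cds)
    ids = sorted(cds)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            hits = local_align(cds[ga], cds[gb], p)
            passing = [
                h for h in hits
                if h.e_value <= e_max
                and 100.0 * (h.query_end - h.query_start) / len(cds[ga]) >= min_query_coverage
            ]
            if passing:
                graph.add_edge(ga, gb)
    comp_size = {}
    for comp in nx.connected_components(graph):
        for g in comp:
            comp_size[g] = len(comp)
    return comp_size


def essentiality_report(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    ortholog_map: OrthologMap,
    calls: list,
    loss_of_function_genes: set[str] | None = None,
) -> dict[str, FactorReport]:
    """Three essentiality proxies for genes hosting old TEs.

    (1) single-copy fraction from the all-vs-all CDS family graph, (2) Ka/Ks
    (Nei-Gojobori) of ortholog pairs, (3) loss-of-function fraction; TE-host
    groups are each tested against the full gene set.
    """
    index = GeneIndex(genome_a.genes)
    te_by_id = {t.te_id: t for t in genome_a.tes}
    host_status: dict[str, set[str]] = {}
    for c in calls:
        if c.status not in ("orthologous", "non_orthologous"):
            continue
        te = te_by_id.get(c.te_id)
        if te is None:
            continue
        for g in index.overlapping_genes(te.interval):
            host_status.setdefault(g.gene_id, set()).add(c.status)
    groups = {
        "all": [g.gene_id for g in genome_a.genes],
        "with_orthologous_te": sorted(
            g for g, st in host_status.items() if "orthologous" in st
        ),
        "with_non_orthologous_te": sorted(
            g for g, st in host_status.items() if "non_orthologous" in st
        ),
    }
    out: dict[str, FactorReport] = {}

    sizes = gene_family_sizes(genome_a)
    def single_fraction(gene_ids):
        vals = [sizes.get(g, 1) for g in gene_ids]
        return sum(v == 1 for v in vals), len(vals)
    base_single, base_n = single_fraction(groups["all"])
    for name in ("with_orthologous_te", "with_non_orthologous_te"):
        s, n = single_fraction(groups[name])
        if n == 0:
            warnings.warn(f"essentiality group {name!r} empty; skipped")
            continue
        table = np.array([[s, n - s], [base_single, base_n - base_single]], float)
        stat, p = chi2_2x2(table)
        out[f"single_copy:{name}"] = FactorReport(
            factor=f"single_copy:{name}", test="chi2_1df", statistic=stat,
            p_value=p, df=1, table=table,
            groups={name: {"n": n, "single_copy_fraction": s / n},
                    "all": {"n": base_n, "single_copy_fraction": base_single / base_n}},
        )

    a_to_b = ortholog_map.a_to_b
    genes_b = {g.gene_id: g for g in genome_b.genes}
    genes_a = {g.gene_id: g for g in genome_a.genes}
    ratios: dict[str, float] = {}
    excluded = 0
    for ga_id, gb_id in sorted(a_to_b.items()):
        ga, gb = genes_a.get(ga_id), genes_b.get(gb_id)
        if ga is None or gb is None:
            continue
        cds_a = "".join(genome_a.sequence_of(c) for c in ga.cds_intervals)
        cds_b = "".join(genome_b.sequence_of(c) for c in gb.cds_intervals)
        _, _, ratio = nei_gojobori(cds_a, cds_b)
        if ratio is None:
            excluded += 1
            continue
        ratios[ga_id] = ratio
    kaks_groups = {
        name: [ratios[g] for g in ids if g in ratios]
        for name, ids in groups.items()
    }
    nonempty = {g: v for g, v in kaks_groups.items() if len(v) >= 2}
    if len(nonempty) >= 2:
        arrays = [np.asarray(nonempty[g]) for g in sorted(nonempty)]
        try:
            h, p = stats.kruskal(*arrays)
        except ValueError:
            h, p = 0.0, 1.0
        out["kaks"] = FactorReport(
            factor="kaks", test="kruskal_wallis", statistic=float(h),
            p_value=float(p), df=len(nonempty) - 1,
            groups={g: {"n": len(v), "mean": float(np.mean(v))}
                    for g, v in sorted(nonempty.items())},
            pairwise=_nemenyi({g: np.asarray(v) for g, v in nonempty.items()}),
            extra={"ks_zero_excluded": excluded},
        )
    else:
        warnings.warn("Ka/Ks comparison skipped: fewer than 2 usable groups")

    if loss_of_function_genes is not None:
        lof = set(loss_of_function_genes)
        base_l = sum(g in lof for g in groups["all"])
        for name in ("with_orthologous_te", "with_non_orthologous_te"):
            ids = groups[name]
            if not ids:
                continue
            l = sum(g in lof for g in ids)
            table = np.array([[l, len(ids) - l], [base_l, base_n - base_l]], float)
            stat, p = chi2_2x2(table)
            out[f"lof:{name}"] = FactorReport(
                factor=f"lof:{name}", test="chi2_1df", statistic=stat, p_value=p,
                df=1, table=table,
                groups={name: {"n": len(ids), "lof_fraction": l / len(ids)},
                        "all": {"n": base_n, "lof_fraction": base_l / base_n}},
            )
    return out
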