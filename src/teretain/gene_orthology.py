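"""One-to-one orthologous gene anchors via reciprocal best protein hits.

Translated CDS from the two genomes are compared all-vs-all with local
BLOSUM62 alignments; a pair is an ortholog anchor iff each protein is the
other's best-scoring hit and the pair passes identity >= 85% with >= 60%
coverage of both sequences.  These anchors later frame the TE orthology
search, so strict one-to-one-ness matters more than sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats import AnnotatedGenome, GeneFeature

__all__ = [
    "TranslationError",
    "OrthologPair",
    "OrthologMap",
    "translate_cds",
    "build_proteome",
    "rbh_ortholog_map",
]


class TranslationError(ValueError):
    """CDS cannot be translated cleanly (frame or internal stop)."""


def translate_cds(gene: GeneFeature, sequences: dict[str, str] | AnnotatedGenome) -> str:
    """Standard-code translation of a gene's concatenated CDS, strand-aware.

    Raises :class:`TranslationError` when the concatenated CDS length is not
    a multiple of 3 or an internal stop codon appears; a trailing stop is
    trimmed.
    """
    seqs = sequences.sequences if isinstance(sequences, AnnotatedGenome) else sequences
    if not gene.cds_intervals:
        raise TranslationError(f"gene {gene.gene_id} has no CDS")
    parts = [seqs[c.scaffold_id][c.start : c.end] for c in gene.cds_intervals]
    cds = "".join(parts).upper()
    if gene.interval.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    if len(cds) % 3 != 0:
        raise TranslationError(
            f"gene {gene.gene_id}: CDS length {len(cds)} not a multiple of 3"
        )
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise TranslationError(f"gene {gene.gene_id}: internal stop codon")
    if not protein:
        raise TranslationError(f"gene {gene.gene_id}: empty translation")
    return protein


def build_proteome(genome: AnnotatedGenome) -> dict[str, str]:
    """Translate every gene, excluding (with a warning) untranslatable ones."""
    proteome: dict[str, str] = {}
    dropped = 0
    for gene in genome.genes:
        try:
            proteome[gene.gene_id] = translate_cds(gene, genome)
        except TranslationError:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{genome.label}: excluded {dropped} untranslatable gene(s) from proteome"
        )
    return proteome


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    score: float


@dataclass
class OrthologMap:
    pairs: list[OrthologPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_ids = [p.gene_a for p in self.pairs]
        b_ids = [p.gene_b for p in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("ortholog map is not one-to-one")

    @property
    def a_to_b(self) -> dict[str, str]:
        return {p.gene_a: p.gene_b for p in self.pairs}

    @property
    def b_to_a(self) -> dict[str, str]:
        return {p.gene_b: p.gene_a for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # blastp-like: gap of length L costs 11 + L
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(aligner, pa: str, pb: str) -> tuple[float, float, float, float]:
    """(score, identity%, coverage_a%, coverage_b%) of the best local alignment."""
    alignment = aligner.align(pa, pb)[0]
    blocks_a, blocks_b = alignment.aligned
    matches = columns = 0
    for (s1, e1), (s2, e2) in zip(blocks_a, blocks_b):
        seg_a, seg_b = pa[s1:e1], pb[s2:e2]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += e1 - s1
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    identity = 100.0 * matches / columns if columns else 0.0
    return (
        float(alignment.score),
        identity,
        100.0 * span_a / len(pa),
        100.0 * span_b / len(pb),
    )


def rbh_ortholog_map(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_identity: float = 85.0,
    min_coverage: float = 60.0,
    min_score: float | None = None,
) -> OrthologMap:
    """Reciprocal-best-hit ortholog map between two proteomes.

    Best hits are by raw alignment score; ties are broken by higher identity
    and then lexicographic id so results are deterministic.  ``min_score``
    optionally imposes a raw-score floor on retained pairs (off by default).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    aligner = _protein_aligner()
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)

    # exact-word prefilter: only pairs sharing a 6-mer are aligned; pairs
    # without one cannot be credible hits and score -1 (never a best hit)
    def words(seq: str, k: int = 6) -> set[str]:
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    words_a = {a: words(proteome_a[a]) for a in ids_a}
    words_b = {b: words(proteome_b[b]) for b in ids_b}
    scores: dict[tuple[str, str], float] = {}
    for a in ids_a:
        pa = proteome_a[a]
        for b in ids_b:
            if words_a[a].isdisjoint(words_b[b]):
                scores[(a, b)] = -1.0
            else:
                scores[(a, b)] = float(aligner.score(pa, proteome_b[b]))

    def _best(candidates: list[tuple[float, str]], seq: str, other: dict[str, str], flip: bool) -> str | None:
        top = max(s for s, _ in candidates)
        if top < 0:
            return None
        tied = sorted(name for s, name in candidates if s == top)
        if len(tied) > 1:
            def ident(name: str) -> float:
                x, y = (other[name], seq) if flip else (seq, other[name])
                return _alignment_stats(aligner, x, y)[1]
            tied.sort(key=lambda name: (-ident(name), name))
        return tied[0]

    best_a = {
        a: _best([(scores[(a, b)], b) for b in ids_b], proteome_a[a], proteome_b, False)
        for a in ids_a
    }
    best_b = {
        b: _best([(scores[(a, b)], a) for a in ids_a], proteome_b[b], proteome_a, True)
        for b in ids_b
    }
    pairs = []
    for a in ids_a:
        b = best_a[a]
        if b is None or best_b[b] != a:
            continue
        score, identity, cov_a, cov_b = _alignment_stats(
            aligner, proteome_a[a], proteome_b[b]
        )
        if identity < min_identity or cov_a < min_coverage or cov_b < min_coverage:
            continue
        if min_score is not None and score < min_score:
            continue
        pairs.append(OrthologPair(a, b, identity, cov_a, cov_b, score))
    return OrthologMap(pairs)
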