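"""Synteny-anchored TE orthology calling between two annotated genomes.

For each TE copy the counterpart region expected to hold its ortholog is
located purely by positional information: the nearest one-to-one orthologous
gene on each side ("framed" TEs, intergenic segments capped at 70 kb in
either genome) or the unambiguous ortholog of the host gene ("inserted"
TEs).  The TE sequence is then searched against that region with a relaxed
local alignment (E <= 1e-10, identity >= 80%); a passing hit overlapping a
counterpart TE annotation of the same family makes the TE orthologous, a hit
overlapping only other families discards it as ambiguous, and everything
else is non-orthologous, i.e. deleted from (or never present in) the other
lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from ._align import AlignParams, AlignmentHit, local_align
from .formats import AnnotatedGenome, GeneFeature, GenomicInterval, TECopy
from .gene_orthology import OrthologMap
from .te_age import classify_age

__all__ = [
    "OrthologyThresholds",
    "Frame",
    "OrthologyCall",
    "PairwiseResult",
    "OrthologySummary",
    "frame_tes",
    "call_orthology",
    "run_pairwise",
    "summarize_calls",
    "orthologous_share_percent",
]

FRAMED, INSERTED = "framed", "inserted"
ORTHOLOGOUS, NON_ORTHOLOGOUS, DISCARDED = "orthologous", "non_orthologous", "discarded"

DISCARD_REASONS = (
    "scaffold_extremity",
    "no_ortholog_scaffold",
    "segment_too_long",
    "ambiguous_family",
    "host_gene_unmapped",
    "none",
)


@dataclass(frozen=True)
class OrthologyThresholds:
    max_segment: int = 70_000
    e_max: float = 1e-10
    min_identity: float = 80.0
    require_same_family: bool = True
    age_threshold: float = 90.0
    align_params: AlignParams = field(default_factory=AlignParams)


@dataclass
class Frame:
    """Resolved search context for one TE in the counterpart genome."""

    te: TECopy
    kind: str                       # framed | inserted
    search_interval: GenomicInterval | None   # counterpart region to scan
    query_span: GenomicInterval | None = None  # intergenic span in query genome
    anchors: tuple[str, ...] = ()   # flanking gene ids (framed) or host gene id


@dataclass
class OrthologyCall:
    te_id: str
    status: str
    discard_reason: str = "none"
    best_hit: AlignmentHit | None = None
    matched_te_id: str | None = None
    kind: str | None = None
    age_class: str | None = None
    identity_to_consensus: float | None = None

    def __post_init__(self) -> None:
        if (self.status == DISCARDED) != (self.discard_reason != "none"):
            raise ValueError("discard_reason must be set iff status is discarded")
        if self.matched_te_id is not None and self.status != ORTHOLOGOUS:
            raise ValueError("matched_te_id only valid for orthologous calls")


# ---------------------------------------------------------------------------
# Framing
# ---------------------------------------------------------------------------

def _pick_host_gene(te: TECopy, genes: list[GeneFeature]) -> GeneFeature:
    def overlap(g: GeneFeature) -> int:
        return min(te.interval.end, g.interval.end) - max(te.interval.start, g.interval.start)

    return max(genes, key=lambda g: (overlap(g), g.gene_id))


def _counterpart_gap(
    ga: GeneFeature, gb: GeneFeature
) -> tuple[str, GenomicInterval | None]:
    """Intergenic segment between two counterpart anchor genes.

    Returns ("ok", interval), ("empty", None) when the anchors abut and
    leave no sequence to search, or ("broken", None) when they do not
    delimit a single segment (different scaffolds / overlapping anchors).
    """
    if ga.interval.scaffold_id != gb.interval.scaffold_id:
        return "broken", None
    if ga.interval.overlaps(gb.interval):
        return "broken", None
    lo = min(ga.interval.end, gb.interval.end)
    hi = max(ga.interval.start, gb.interval.start)
    if hi <= lo:
        return "empty", None
    return "ok", GenomicInterval(ga.interval.scaffold_id, lo, hi)


def frame_tes(
    genome: AnnotatedGenome,
    counterpart: AnnotatedGenome,
    ortholog_map: dict[str, str],
    max_segment: int = 70_000,
) -> tuple[list[Frame], list[OrthologyCall]]:
    """Assign each TE a search frame in the counterpart genome.

    Returns the resolved frames plus the discarded calls (scaffold
    extremities, scaffolds without mapped genes, over-long segments,
    unmapped host genes).  Gene overlap takes precedence: a TE touching an
    anchor gene is treated as inserted in it.
    """
    counterpart_genes = {g.gene_id: g for g in counterpart.genes}
    genes_by_sc = genome.genes_by_scaffold()
    mapped_by_sc = {
        sc: [g for g in glist if g.gene_id in ortholog_map]
        for sc, glist in genes_by_sc.items()
    }
    frames: list[Frame] = []
    discarded: list[OrthologyCall] = []

    def discard(te: TECopy, reason: str, kind: str | None) -> None:
        discarded.append(
            OrthologyCall(
                te.te_id, DISCARDED, reason, kind=kind,
                age_class=_age_of(te), identity_to_consensus=te.identity_to_consensus,
            )
        )

    for te in genome.tes:
        sc = te.interval.scaffold_id
        overlapping = [
            g for g in genes_by_sc.get(sc, []) if g.interval.overlaps(te.interval)
        ]
        if overlapping:
            mapped_hosts = [g for g in overlapping if g.gene_id in ortholog_map]
            if not mapped_hosts:
                discard(te, "host_gene_unmapped", INSERTED)
                continue
            host = _pick_host_gene(te, mapped_hosts)
            ortho = counterpart_genes.get(ortholog_map[host.gene_id])
            if ortho is None:
                discard(te, "host_gene_unmapped", INSERTED)
                continue
            frames.append(
                Frame(te, INSERTED, ortho.interval, anchors=(host.gene_id,))
            )
            continue
        mapped = mapped_by_sc.get(sc, [])
        if not mapped:
            discard(te, "no_ortholog_scaffold", FRAMED)
            continue
        left = None
        right = None
        for g in mapped:
            if g.interval.end <= te.interval.start:
                if left is None or g.interval.end > left.interval.end:
                    left = g
            elif g.interval.start >= te.interval.end:
                if right is None or g.interval.start < right.interval.start:
                    right = g
        if left is None or right is None:
            discard(te, "scaffold_extremity", FRAMED)
            continue
        query_span = GenomicInterval(sc, left.interval.end, right.interval.start)
        ca = counterpart_genes.get(ortholog_map[left.gene_id])
        cb = counterpart_genes.get(ortholog_map[right.gene_id])
        if ca is None or cb is None:
            discard(te, "no_ortholog_scaffold", FRAMED)
            continue
        gap_status, counter_span = _counterpart_gap(ca, cb)
        if gap_status == "broken":
            discard(te, "no_ortholog_scaffold", FRAMED)
            continue
        counter_len = counter_span.length if counter_span is not None else 0
        if query_span.length > max_segment or counter_len > max_segment:
            discard(te, "segment_too_long", FRAMED)
            continue
        frames.append(
            Frame(te, FRAMED, counter_span, query_span,
                  anchors=(left.gene_id, right.gene_id))
        )
    return frames, discarded


def _age_of(te: TECopy) -> str | None:
    if te.identity_to_consensus is None:
        return None
    return classify_age(te.identity_to_consensus)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _te_interval_trees(genome: AnnotatedGenome) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for te in genome.tes:
        trees.setdefault(te.interval.scaffold_id, IntervalTree()).addi(
            te.interval.start, te.interval.end, te
        )
    return trees


def call_orthology(
    frame: Frame,
    genome: AnnotatedGenome,
    counterpart: AnnotatedGenome,
    thresholds: OrthologyThresholds | None = None,
    counterpart_te_trees: dict[str, IntervalTree] | None = None,
) -> OrthologyCall:
    """Decide orthologous / non_orthologous / discarded for one framed TE.

    Passing hits (E and identity thresholds) are walked best-E-value first;
    the first hit overlapping any counterpart TE annotation decides: same
    family -> orthologous, different family only -> discarded(ambiguous_family).
    No passing hit over a TE annotation -> non_orthologous.
    """
    th = thresholds or OrthologyThresholds()
    te = frame.te
    base = dict(kind=frame.kind, age_class=_age_of(te),
                identity_to_consensus=te.identity_to_consensus)
    region = frame.search_interval
    if region is None or region.length < th.align_params.k:
        return OrthologyCall(te.te_id, NON_ORTHOLOGOUS, **base)
    trees = counterpart_te_trees or _te_interval_trees(counterpart)
    query_seq = genome.sequence_of(te.interval)
    subject_seq = counterpart.sequence_of(region)
    hits = local_align(query_seq, subject_seq, th.align_params)
    passing = [
        h for h in hits if h.e_value <= th.e_max and h.identity >= th.min_identity
    ]
    tree = trees.get(region.scaffold_id, IntervalTree())
    unannotated_hit = None  # best passing hit over annotation-free sequence
    for hit in passing:
        lo = region.start + hit.subject_start
        hi = region.start + hit.subject_end
        touched = sorted(
            (iv.data for iv in tree.overlap(lo, hi)),
            key=lambda t: -(min(hi, t.interval.end) - max(lo, t.interval.start)),
        )
        if not touched:
            if unannotated_hit is None:
                unannotated_hit = hit
            continue
        if not th.require_same_family:
            return OrthologyCall(
                te.te_id, ORTHOLOGOUS, best_hit=hit,
                matched_te_id=touched[0].te_id, **base,
            )
        same_family = [t for t in touched if t.family_id == te.family_id]
        if same_family:
            return OrthologyCall(
                te.te_id, ORTHOLOGOUS, best_hit=hit,
                matched_te_id=same_family[0].te_id, **base,
            )
        return OrthologyCall(
            te.te_id, DISCARDED, "ambiguous_family", best_hit=hit, **base
        )
    # a recorded best_hit on a non-orthologous call marks the "passing hit
    # over unannotated sequence" case, countable downstream
    return OrthologyCall(te.te_id, NON_ORTHOLOGOUS, best_hit=unannotated_hit, **base)


# ---------------------------------------------------------------------------
# Pairwise run and summaries
# ---------------------------------------------------------------------------

@dataclass
class OrthologySummary:
    """Status x age cross-tabulation for one calling direction."""

    old_orthologous: int = 0
    young_orthologous: int = 0
    old_non_orthologous: int = 0
    young_non_orthologous: int = 0
    discarded: int = 0
    discard_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def total_orthologous(self) -> int:
        return self.old_orthologous + self.young_orthologous

    @property
    def total_non_orthologous(self) -> int:
        return self.old_non_orthologous + self.young_non_orthologous

    @property
    def interrogated(self) -> int:
        return self.total_orthologous + self.total_non_orthologous

    @property
    def orthologous_share_percent(self) -> float:
        return orthologous_share_percent(self.total_orthologous, self.interrogated)


def orthologous_share_percent(n_orthologous: int, n_interrogated: int) -> float:
    """Orthologous share of interrogated TEs, in percent to one decimal."""
    if n_interrogated <= 0:
        raise ValueError("no interrogated TEs")
    return round(100.0 * n_orthologous / n_interrogated, 1)


def summarize_calls(calls: list[OrthologyCall]) -> OrthologySummary:
    s = OrthologySummary()
    for c in calls:
        if c.status == DISCARDED:
            s.discarded += 1
            s.discard_reasons[c.discard_reason] = (
                s.discard_reasons.get(c.discard_reason, 0) + 1
            )
        elif c.status == ORTHOLOGOUS:
            if c.age_class == "young":
                s.young_orthologous += 1
            else:
                s.old_orthologous += 1
        else:
            if c.age_class == "young":
                s.young_non_orthologous += 1
            else:
                s.old_non_orthologous += 1
    return s


@dataclass
class PairwiseResult:
    calls_a: list[OrthologyCall]
    calls_b: list[OrthologyCall]
    summary_a: OrthologySummary
    summary_b: OrthologySummary


def run_pairwise(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    ortholog_map: OrthologMap,
    thresholds: OrthologyThresholds | None = None,
) -> PairwiseResult:
    """Call TE orthology in both directions (A vs B, then B vs A)."""
    th = thresholds or OrthologyThresholds()
    results = []
    for genome, counterpart, gmap in (
        (genome_a, genome_b, ortholog_map.a_to_b),
        (genome_b, genome_a, ortholog_map.b_to_a),
    ):
        frames, discarded = frame_tes(genome, counterpart, gmap, th.max_segment)
        trees = _te_interval_trees(counterpart)
        calls = list(discarded)
        for frame in frames:
            calls.append(
                call_orthology(frame, genome, counterpart, th, trees)
            )
        calls.sort(key=lambda c: c.te_id)
        results.append(calls)
    return PairwiseResult(
        results[0], results[1], summarize_calls(results[0]), summarize_calls(results[1])
    )
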