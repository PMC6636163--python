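"""Shared genome/feature model and on-disk formats.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive.  Strand is recorded on features but deliberately ignored by all
overlap and distance logic: the retention analyses are strand-agnostic.

TE annotations travel as GFF3 ``dispersed_repeat`` features carrying
``family_id``, ``superfamily`` and (optionally) ``identity`` attributes;
genes are ``gene`` features with ``CDS`` children linked by ``Parent``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "SUPERFAMILIES",
    "GenomicInterval",
    "GeneFeature",
    "TECopy",
    "AnnotatedGenome",
    "read_fasta",
    "write_fasta",
    "read_genome_annotation",
    "write_genome_annotation",
    "classify_te_location",
    "nearest_gene_distance",
]

#: Controlled vocabulary of TE superfamilies used throughout the pipeline.
SUPERFAMILIES = ("Gypsy", "Copia", "LINE", "MuDR", "Helitron", "SINE")

_IUPAC_NT = set("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent annotations."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.scaffold_id:
            raise FormatError("interval with empty scaffold_id")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.scaffold_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between interval boundaries; 0 if abutting/overlapping."""
        if self.scaffold_id != other.scaffold_id:
            raise ValueError("gap_to requires intervals on the same scaffold")
        return max(0, other.start - self.end, self.start - other.end)


@dataclass
class GeneFeature:
    gene_id: str
    interval: GenomicInterval
    cds_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cds in self.cds_intervals:
            if not (
                cds.scaffold_id == self.interval.scaffold_id
                and self.interval.start <= cds.start
                and cds.end <= self.interval.end
            ):
                raise FormatError(
                    f"CDS {cds} of gene {self.gene_id} outside gene interval"
                )
        ivs = sorted((c.start, c.end) for c in self.cds_intervals)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping CDS intervals in gene {self.gene_id}")


@dataclass
class TECopy:
    """A located TE fragment tied to a family consensus."""

    te_id: str
    interval: GenomicInterval
    family_id: str
    superfamily: str
    identity_to_consensus: float | None = None

    def __post_init__(self) -> None:
        if self.superfamily not in SUPERFAMILIES:
            raise FormatError(
                f"unknown superfamily {self.superfamily!r} for TE {self.te_id}"
            )
        if self.identity_to_consensus is not None and not (
            0.0 <= self.identity_to_consensus <= 100.0
        ):
            raise FormatError(
                f"identity out of range for TE {self.te_id}: "
                f"{self.identity_to_consensus}"
            )

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class AnnotatedGenome:
    label: str
    sequences: dict[str, str]
    genes: list[GeneFeature] = field(default_factory=list)
    tes: list[TECopy] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for feat_id, interval in self._iter_features():
            if feat_id in seen:
                raise FormatError(f"duplicate feature id {feat_id} in {self.label}")
            seen.add(feat_id)
            seq = self.sequences.get(interval.scaffold_id)
            if seq is None:
                raise FormatError(
                    f"feature {feat_id} references unknown scaffold "
                    f"{interval.scaffold_id}"
                )
            if interval.end > len(seq):
                raise FormatError(
                    f"feature {feat_id} ({interval.start}-{interval.end}) exceeds "
                    f"scaffold {interval.scaffold_id} length {len(seq)}"
                )

    def _iter_features(self):
        for g in self.genes:
            yield g.gene_id, g.interval
        for t in self.tes:
            yield t.te_id, t.interval

    def sequence_of(self, interval: GenomicInterval) -> str:
        """Forward-strand sequence slice of the interval."""
        return self.sequences[interval.scaffold_id][interval.start : interval.end]

    def genes_by_scaffold(self) -> dict[str, list[GeneFeature]]:
        out: dict[str, list[GeneFeature]] = {}
        for g in self.genes:
            out.setdefault(g.interval.scaffold_id, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.interval.start, g.interval.end))
        return out

    def tes_by_scaffold(self) -> dict[str, list[TECopy]]:
        out: dict[str, list[TECopy]] = {}
        for t in self.tes:
            out.setdefault(t.interval.scaffold_id, []).append(t)
        for lst in out.values():
            lst.sort(key=lambda t: (t.interval.start, t.interval.end))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping.

    Ids are the first whitespace-delimited header token; insertion order is
    preserved.  Duplicate ids, empty files and non-IUPAC characters raise
    :class:`FormatError` naming the offending record.
    """
    sequences: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise FormatError(
                f"non-IUPAC character(s) {sorted(bad)} in record {current!r}"
            )
        sequences[current] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise FormatError("FASTA header with empty id")
                if current in sequences:
                    raise FormatError(f"duplicate FASTA id {current!r}")
                chunks = []
            else:
                if current is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
    _flush()
    if not sequences:
        raise FormatError(f"empty FASTA file: {path}")
    return sequences


def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TE_TYPE = "dispersed_repeat"


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def write_genome_annotation(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    """Write the genome as FASTA + GFF3 (1-based inclusive on disk)."""
    write_fasta(fasta_path, genome.sequences)
    lines = ["##gff-version 3"]
    feats: list[tuple[str, int, int, str]] = []
    for g in genome.genes:
        iv = g.interval
        feats.append(
            (
                iv.scaffold_id,
                iv.start,
                0,
                "\t".join(
                    [
                        iv.scaffold_id,
                        "teretain",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        _fmt_attrs({"ID": g.gene_id}),
                    ]
                ),
            )
        )
        for j, cds in enumerate(g.cds_intervals):
            feats.append(
                (
                    iv.scaffold_id,
                    cds.start,
                    1,
                    "\t".join(
                        [
                            cds.scaffold_id,
                            "teretain",
                            "CDS",
                            str(cds.start + 1),
                            str(cds.end),
                            ".",
                            cds.strand,
                            ".",
                            _fmt_attrs({"ID": f"{g.gene_id}.cds{j}", "Parent": g.gene_id}),
                        ]
                    ),
                )
            )
    for t in genome.tes:
        iv = t.interval
        attrs = {"ID": t.te_id, "family_id": t.family_id, "superfamily": t.superfamily}
        if t.identity_to_consensus is not None:
            attrs["identity"] = f"{t.identity_to_consensus:.3f}"
        feats.append(
            (
                iv.scaffold_id,
                iv.start,
                2,
                "\t".join(
                    [
                        iv.scaffold_id,
                        "teretain",
                        _TE_TYPE,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                ),
            )
        )
    feats.sort(key=lambda x: (x[0], x[1], x[2]))
    lines.extend(f[3] for f in feats)
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genome_annotation(fasta_path, gff3_path, label: str | None = None) -> AnnotatedGenome:
    """Load FASTA + GFF3 into an :class:`AnnotatedGenome`.

    Accepts ``gene``/``CDS``/``dispersed_repeat`` features; CDS rows are
    grouped under their ``Parent`` gene.  A TE lying wholly inside a CDS is a
    legal, meaningful annotation and is kept.
    """
    sequences = read_fasta(fasta_path)
    genes: dict[str, GeneFeature] = {}
    cds_rows: list[tuple[str, GenomicInterval]] = []
    tes: list[TECopy] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{gff3_path}:{lineno}: expected 9 columns")
            scaffold, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
            attrs = _parse_attrs(attr_text)
            if scaffold not in sequences:
                raise FormatError(
                    f"{gff3_path}:{lineno}: unknown scaffold {scaffold!r}"
                )
            iv = GenomicInterval(scaffold, int(start) - 1, int(end), strand)
            if iv.end > len(sequences[scaffold]):
                raise FormatError(
                    f"{gff3_path}:{lineno}: feature end {iv.end} exceeds scaffold "
                    f"length {len(sequences[scaffold])}"
                )
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise FormatError(f"{gff3_path}:{lineno}: gene without ID")
                genes[gid] = GeneFeature(gid, iv, [])
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError(f"{gff3_path}:{lineno}: CDS without Parent gene")
                cds_rows.append((parent, iv))
            elif ftype == _TE_TYPE:
                tid = attrs.get("ID")
                if not tid:
                    raise FormatError(f"{gff3_path}:{lineno}: TE without ID")
                identity = attrs.get("identity")
                tes.append(
                    TECopy(
                        tid,
                        iv,
                        attrs.get("family_id", ""),
                        attrs.get("superfamily", ""),
                        float(identity) if identity is not None else None,
                    )
                )
    for parent, iv in cds_rows:
        if parent not in genes:
            raise FormatError(f"CDS with unknown parent gene {parent!r}")
        genes[parent].cds_intervals.append(iv)
    gene_list = []
    for g in genes.values():
        g.cds_intervals.sort(key=lambda c: c.start)
        gene_list.append(GeneFeature(g.gene_id, g.interval, g.cds_intervals))
    return AnnotatedGenome(
        label=label or str(gff3_path), sequences=sequences, genes=gene_list, tes=tes
    )


# ---------------------------------------------------------------------------
# Genic context
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval-tree index over genes and their CDS exons, per scaffold."""

    def __init__(self, genes: Iterable[GeneFeature]):
        self._gene_trees: dict[str, IntervalTree] = {}
        self._cds_trees: dict[str, IntervalTree] = {}
        self._bounds: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            sc = g.interval.scaffold_id
            self._gene_trees.setdefault(sc, IntervalTree()).addi(
                g.interval.start, g.interval.end, g
            )
            for cds in g.cds_intervals:
                self._cds_trees.setdefault(sc, IntervalTree()).addi(
                    cds.start, cds.end, g
                )
            self._bounds.setdefault(sc, []).append((g.interval.start, g.interval.end))
        for lst in self._bounds.values():
            lst.sort()

    def overlapping_genes(self, iv: GenomicInterval) -> list[GeneFeature]:
        tree = self._gene_trees.get(iv.scaffold_id)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=lambda g: (g.interval.start, g.gene_id))

    def overlaps_cds(self, iv: GenomicInterval) -> bool:
        tree = self._cds_trees.get(iv.scaffold_id)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def nearest_gap(self, iv: GenomicInterval) -> int | None:
        bounds = self._bounds.get(iv.scaffold_id)
        if not bounds:
            return None
        best = None
        for s, e in bounds:
            gap = max(0, s - iv.end, iv.start - e)
            if best is None or gap < best:
                best = gap
        return best


def classify_te_location(
    te: TECopy, genes: Iterable[GeneFeature] | GeneIndex
) -> str:
    """Classify a TE as ``genic_cds``, ``genic_noncds`` or ``intergenic``.

    Any >= 1 bp overlap with a CDS exon wins; otherwise >= 1 bp overlap with a
    gene interval makes it genic_noncds; otherwise intergenic.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if index.overlaps_cds(te.interval):
        return "genic_cds"
    if index.overlapping_genes(te.interval):
        return "genic_noncds"
    return "intergenic"


def nearest_gene_distance(
    te: TECopy, genes: Iterable[GeneFeature] | GeneIndex
) -> int | None:
    """Minimum bp gap between the TE and any gene on its scaffold.

    Returns 0 for abutting (or overlapping) features and ``None`` when the
    scaffold carries no gene.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.nearest_gap(te.interval)
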