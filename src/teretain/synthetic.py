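"""Synthetic genome pairs with known TE fates.

The generator emulates the comparative setting the pipeline is built for:
an ancestral genome carrying a multi-superfamily TE complement with a
bimodal age structure (an "old" identity component around 80% and a "young"
one around 97%, mirroring the two populations such genomes show around the
90% antimode), evolved into two descendant lineages by neutral substitution
(1-5% total divergence), small intergenic indels, lineage-specific TE
deletion with genic sheltering (the deletion probability of a genic TE is
multiplied by a factor <= 1), and lineage-specific young insertions.  Every
ancestral copy's fate in each lineage is recorded in a truth table that
downstream orthology calls are scored against.

Design constraints worth knowing:

* TE deletion removes exactly the annotated interval (clean excision); an
  optional flank parameter widens deletions to stress the sheltering logic.
* Substitutions in CDS never create premature stop codons and indels are
  restricted to feature-free intergenic DNA - a crude but effective stand-in
  for purifying selection that keeps gene anchors translatable and TE
  identity bookkeeping positional.
* Copies inserted into CDS are padded to a codon boundary and recoded to be
  stop-free in frame, so host genes remain valid ORFs and clean excision
  restores one.
* All features are emitted on the forward strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    SUPERFAMILIES,
    AnnotatedGenome,
    GeneFeature,
    GeneIndex,
    GenomicInterval,
    TECopy,
    classify_te_location,
)

__all__ = [
    "SimulationConfig",
    "TruthRow",
    "TruthTable",
    "simulate_ancestor",
    "evolve_pair",
    "simulate_side_tables",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_SUPERFAMILY_WEIGHTS = {
    "Gypsy": 0.28,
    "Copia": 0.22,
    "LINE": 0.15,
    "MuDR": 0.15,
    "Helitron": 0.15,
    "SINE": 0.05,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 500_000
    n_genes: int = 150
    n_ancestral_tes: int = 1500
    superfamily_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPERFAMILY_WEIGHTS)
    )
    families_per_superfamily: int = 25
    consensus_length_range: tuple[int, int] = (800, 4000)
    te_length_log_mean: float = math.log(350.0)
    te_length_log_sd: float = 0.7
    te_min_length: int = 80
    # two-component identity mixture: (weight, mean, sd) old then young
    age_old: tuple[float, float, float] = (0.7, 80.0, 5.0)
    age_young: tuple[float, float, float] = (0.3, 97.0, 1.5)
    # where ancestral copies sit: intergenic / intron / CDS
    location_mix: tuple[float, float, float] = (0.70, 0.18, 0.12)
    substitution_rate_between_species: float = 0.02
    indel_rate: float = 2e-4
    deletion_prob_intergenic: float = 0.30
    genic_sheltering_factor: float = 0.3
    deletion_flank_bp: int = 0
    n_new_insertions: int = 50
    new_insertion_identity_min: float = 95.0
    min_spacer: int = 60
    # side tables
    sirna_contrast: float = 1.0
    meth_contrast: float = 1.0
    expression_contrast: float = 1.0
    meth_site_coverage: float = 0.3
    n_accessions: int = 20
    n_true_insertions: int = 20
    n_noise_sites: int = 50
    mobilome_min_carrier_support: int = 2

    def validate(self) -> None:
        w = self.superfamily_weights
        if set(w) - set(SUPERFAMILIES):
            raise ValueError(f"unknown superfamilies in weights: {set(w) - set(SUPERFAMILIES)}")
        if abs(sum(w.values()) - 1.0) > 1e-6:
            raise ValueError("superfamily_weights must sum to 1")
        for name in (
            "deletion_prob_intergenic", "genic_sheltering_factor", "indel_rate",
            "meth_site_coverage",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.substitution_rate_between_species <= 0.1):
            raise ValueError("substitution_rate_between_species must be in [0, 0.1]")
        if abs(sum(self.location_mix) - 1.0) > 1e-6:
            raise ValueError("location_mix must sum to 1")


# ---------------------------------------------------------------------------
# Low-level sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _ACGT[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, identity_target: float) -> str:
    """Substitute bases at rate 1 - identity/100 (always to a different base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = 1.0 - identity_target / 100.0
    hit = np.flatnonzero(rng.random(arr.shape[0]) < p)
    if hit.size:
        codes = np.searchsorted(_ACGT, arr[hit])  # ACGT are sorted bytes
        arr[hit] = _ACGT[(codes + rng.integers(1, 4, hit.size)) % 4]
    return arr.tobytes().decode()


def _hamming_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    x = np.frombuffer(a[:n].encode(), np.uint8)
    y = np.frombuffer(b[:n].encode(), np.uint8)
    return 100.0 * float(np.mean(x == y))


def _codon_sanitize(seq: str) -> str:
    """Trim to a codon multiple and recode in-frame stops (third base -> C)."""
    seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    out = [c[:2] + "C" if c in _STOPS else c for c in codons]
    return "".join(out)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


# ---------------------------------------------------------------------------
# Ancestor simulation
# ---------------------------------------------------------------------------

@dataclass
class _TEProto:
    te_id: str
    family_id: str
    superfamily: str
    seq: str
    cons_start: int
    location: str  # intergenic | intron | cds


def _sample_identity(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    w_old = cfg.age_old[0] / (cfg.age_old[0] + cfg.age_young[0])
    comp = cfg.age_old if rng.random() < w_old else cfg.age_young
    return float(np.clip(rng.normal(comp[1], comp[2]), 60.0, 100.0))


def _make_library(rng: np.random.Generator, cfg: SimulationConfig):
    library: dict[str, str] = {}
    fam_superfamily: dict[str, str] = {}
    for sf in SUPERFAMILIES:
        if cfg.superfamily_weights.get(sf, 0.0) <= 0:
            continue
        for i in range(cfg.families_per_superfamily):
            fam = f"{sf}_fam{i:03d}"
            length = int(rng.integers(*cfg.consensus_length_range))
            library[fam] = _random_seq(rng, length)
            fam_superfamily[fam] = sf
    return library, fam_superfamily


def _sample_te_protos(rng, cfg, library, fam_superfamily) -> list[_TEProto]:
    fams = sorted(library)
    weights = np.array(
        [cfg.superfamily_weights[fam_superfamily[f]] / cfg.families_per_superfamily
         for f in fams]
    )
    weights /= weights.sum()
    locs = ["intergenic", "intron", "cds"]
    protos = []
    for i in range(cfg.n_ancestral_tes):
        fam = fams[rng.choice(len(fams), p=weights)]
        cons = library[fam]
        length = int(
            np.clip(
                rng.lognormal(cfg.te_length_log_mean, cfg.te_length_log_sd),
                cfg.te_min_length,
                len(cons),
            )
        )
        start = int(rng.integers(0, len(cons) - length + 1))
        identity = _sample_identity(rng, cfg)
        seq = _mutate(rng, cons[start : start + length], identity)
        loc = locs[rng.choice(3, p=np.array(cfg.location_mix))]
        if loc == "cds":
            seq = _codon_sanitize(seq)
        protos.append(
            _TEProto(f"te{i:05d}", fam, fam_superfamily[fam], seq, start, loc)
        )
    return protos


class _GeneBuilder:
    """A gene as alternating exon/intron part lists supporting TE insertion."""

    def __init__(self, gene_id: str, rng: np.random.Generator, cfg: SimulationConfig):
        self.gene_id = gene_id
        n_exons = int(rng.integers(2, 5))
        self.exons = []
        for e in range(n_exons):
            n_codons = int(rng.integers(60, 200))
            parts = []
            if e == 0:
                parts.append(["seq", "ATG" + _random_codons(rng, n_codons)])
            elif e == n_exons - 1:
                parts.append(["seq", _random_codons(rng, n_codons) + "TAA"])
            else:
                parts.append(["seq", _random_codons(rng, n_codons)])
            self.exons.append(parts)
        self.introns = [
            [["seq", _random_seq(rng, int(rng.integers(80, 400)))]]
            for _ in range(n_exons - 1)
        ]

    def insert_te(self, proto: _TEProto, rng: np.random.Generator) -> bool:
        if proto.location == "cds":
            pools = self.exons
            unit = 3
            margin = 9
        else:
            pools = self.introns
            unit = 1
            margin = 20
        eligible = [
            (pi, qi)
            for pi, pool in enumerate(pools)
            for qi, part in enumerate(pool)
            if part[0] == "seq" and len(part[1]) >= 2 * margin + unit
        ]
        if not eligible:
            return False
        pi, qi = eligible[int(rng.integers(0, len(eligible)))]
        part = pools[pi][qi]
        seq = part[1]
        n_units = (len(seq) - 2 * margin) // unit
        cut = margin + unit * int(rng.integers(0, n_units + 1))
        pools[pi][qi : qi + 1] = [
            ["seq", seq[:cut]],
            ["te", proto.seq, proto],
            ["seq", seq[cut:]],
        ]
        return True

    def emit(self, scaffold: str, offset: int):
        """Return (sequence, GeneFeature, [(TECopy-args, in_cds)]) at offset."""
        chunks: list[str] = []
        pos = offset
        cds_intervals: list[GenomicInterval] = []
        te_placements = []
        for i, exon in enumerate(self.exons):
            exon_start = pos
            for part in exon:
                if part[0] == "te":
                    te_placements.append((part[2], pos, pos + len(part[1])))
                chunks.append(part[1])
                pos += len(part[1])
            cds_intervals.append(GenomicInterval(scaffold, exon_start, pos, "+"))
            if i < len(self.introns):
                for part in self.introns[i]:
                    if part[0] == "te":
                        te_placements.append((part[2], pos, pos + len(part[1])))
                    chunks.append(part[1])
                    pos += len(part[1])
        gene = GeneFeature(
            self.gene_id, GenomicInterval(scaffold, offset, pos, "+"), cds_intervals
        )
        return "".join(chunks), gene, te_placements


def simulate_ancestor(
    config: SimulationConfig,
) -> tuple[AnnotatedGenome, dict[str, str]]:
    """Build the ancestral annotated genome and its consensus library.

    Raises ``ValueError`` when the requested features cannot be packed into
    the configured scaffolds.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    library, fam_superfamily = _make_library(rng, config)
    protos = _sample_te_protos(rng, config, library, fam_superfamily)

    genes = [_GeneBuilder(f"g{i:04d}", rng, config) for i in range(config.n_genes)]
    intergenic_protos: list[_TEProto] = []
    for proto in protos:
        if proto.location == "intergenic" or not config.n_genes:
            intergenic_protos.append(proto)
            continue
        host = genes[int(rng.integers(0, len(genes)))]
        if not host.insert_te(proto, rng):
            intergenic_protos.append(proto)

    # round-robin items over scaffolds, shuffled placement order per scaffold
    items: list[tuple[str, object]] = [("gene", g) for g in genes] + [
        ("te", p) for p in intergenic_protos
    ]
    order = rng.permutation(len(items))
    per_scaffold: list[list] = [[] for _ in range(config.n_scaffolds)]
    for rank, idx in enumerate(order):
        per_scaffold[rank % config.n_scaffolds].append(items[idx])

    sequences: dict[str, str] = {}
    out_genes: list[GeneFeature] = []
    out_tes: list[TECopy] = []
    te_origin: dict[str, tuple[str, int]] = {}

    for si, scaffold_items in enumerate(per_scaffold):
        scaffold = f"scf{si + 1}"
        lengths = []
        emitted = []
        for kind, obj in scaffold_items:
            if kind == "gene":
                seq, _, _ = obj.emit(scaffold, 0)
                lengths.append(len(seq))
            else:
                lengths.append(len(obj.seq))
        n_slots = len(scaffold_items) + 1
        spare = config.scaffold_length - sum(lengths) - config.min_spacer * n_slots
        if spare < 0:
            raise ValueError(
                f"infeasible packing: scaffold {scaffold} needs "
                f"{sum(lengths) + config.min_spacer * n_slots} bp "
                f"> {config.scaffold_length}"
            )
        spacers = rng.multinomial(spare, np.full(n_slots, 1.0 / n_slots))
        spacers = spacers + config.min_spacer
        chunks = []
        pos = 0
        for slot, (kind, obj) in enumerate(scaffold_items):
            gap = int(spacers[slot])
            chunks.append(_random_seq(rng, gap))
            pos += gap
            if kind == "gene":
                seq, gene, placements = obj.emit(scaffold, pos)
                chunks.append(seq)
                out_genes.append(gene)
                for proto, s, e in placements:
                    out_tes.append(
                        TECopy(
                            proto.te_id,
                            GenomicInterval(scaffold, s, e, "+"),
                            proto.family_id,
                            proto.superfamily,
                            _hamming_identity(
                                seq[s - pos : e - pos],
                                library[proto.family_id][
                                    proto.cons_start : proto.cons_start + (e - s)
                                ],
                            ),
                        )
                    )
                    te_origin[proto.te_id] = (proto.family_id, proto.cons_start)
                pos += len(seq)
            else:
                out_tes.append(
                    TECopy(
                        obj.te_id,
                        GenomicInterval(scaffold, pos, pos + len(obj.seq), "+"),
                        obj.family_id,
                        obj.superfamily,
                        _hamming_identity(
                            obj.seq,
                            library[obj.family_id][
                                obj.cons_start : obj.cons_start + len(obj.seq)
                            ],
                        ),
                    )
                )
                te_origin[obj.te_id] = (obj.family_id, obj.cons_start)
                chunks.append(obj.seq)
                pos += len(obj.seq)
        chunks.append(_random_seq(rng, int(spacers[-1])))
        sequences[scaffold] = "".join(chunks)

    out_genes.sort(key=lambda g: (g.interval.scaffold_id, g.interval.start))
    out_tes.sort(key=lambda t: (t.interval.scaffold_id, t.interval.start))
    genome = AnnotatedGenome("ancestor", sequences, out_genes, out_tes)
    genome.te_origin = te_origin  # positional bookkeeping for identity updates
    return genome, library


# ---------------------------------------------------------------------------
# Descendant lineages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRow:
    ancestral_te_id: str
    fate_a: str  # te id if retained, else "deleted" / "absent"
    fate_b: str
    expected_call: str  # orthologous | non_orthologous | not_interrogated


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.ancestral_te_id, r.fate_a, r.fate_b, r.expected_call) for r in self.rows],
            columns=["ancestral_te_id", "fate_a", "fate_b", "expected_call"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([TruthRow(*row) for row in df.itertuples(index=False)])

    def status_by_te(self, direction: str) -> dict[str, str]:
        """Map surviving te_id in one genome ('a'/'b') -> expected call."""
        col = {"a": "fate_a", "b": "fate_b"}[direction]
        out = {}
        for r in self.rows:
            fate = getattr(r, col)
            if fate not in ("deleted", "absent"):
                out[fate] = r.expected_call
        return out


def _feature_free_gaps(genome: AnnotatedGenome, margin: int = 10):
    gaps: dict[str, list[tuple[int, int]]] = {}
    for sc, seq in genome.sequences.items():
        spans = []
        for g in genome.genes:
            if g.interval.scaffold_id == sc:
                spans.append((g.interval.start, g.interval.end))
        for t in genome.tes:
            if t.interval.scaffold_id == sc:
                spans.append((t.interval.start, t.interval.end))
        spans.sort()
        out = []
        pos = 0
        for s, e in spans + [(len(seq), len(seq))]:
            if s - pos > 2 * margin:
                out.append((pos + margin, s - margin))
            pos = max(pos, e)
        gaps[sc] = out
    return gaps


def _evolve_one(
    ancestor: AnnotatedGenome,
    library: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    label: str,
    genic: dict[str, bool],
):
    """Apply deletion, insertion, indel and substitution to one lineage."""
    fate: dict[str, str] = {}
    deleted: set[str] = set()
    for te in ancestor.tes:
        p = config.deletion_prob_intergenic * (
            config.genic_sheltering_factor if genic[te.te_id] else 1.0
        )
        if rng.random() < p:
            deleted.add(te.te_id)
            fate[te.te_id] = "deleted"
        else:
            fate[te.te_id] = te.te_id

    te_by_id = {t.te_id: t for t in ancestor.tes}
    bounds_by_sc: dict[str, list[tuple[int, int]]] = {}
    for feat_id, iv in ancestor._iter_features():
        bounds_by_sc.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))
    for lst in bounds_by_sc.values():
        lst.sort()

    gaps = _feature_free_gaps(ancestor)
    gap_list = [(sc, s, e) for sc in sorted(gaps) for (s, e) in gaps[sc]]
    gap_weights = np.array([e - s for _, s, e in gap_list], dtype=float)
    gap_weights = gap_weights / gap_weights.sum() if gap_weights.sum() else gap_weights

    # new young lineage-specific insertions
    new_tes: list[tuple[str, int, str, _TEProto]] = []  # scaffold, pos, seq, proto
    fams = sorted(library)
    for i in range(config.n_new_insertions):
        gi = int(rng.choice(len(gap_list), p=gap_weights))
        sc, s, e = gap_list[gi]
        pos = int(rng.integers(s + 1, e - 1))
        fam = fams[int(rng.integers(0, len(fams)))]
        cons = library[fam]
        length = int(
            np.clip(
                rng.lognormal(config.te_length_log_mean, config.te_length_log_sd),
                config.te_min_length,
                len(cons),
            )
        )
        start = int(rng.integers(0, len(cons) - length + 1))
        identity = float(rng.uniform(config.new_insertion_identity_min, 99.8))
        seq = _mutate(rng, cons[start : start + length], identity)
        proto = _TEProto(
            f"{label}new{i:04d}", fam, fam.split("_")[0], seq, start, "intergenic"
        )
        new_tes.append((sc, pos, seq, proto))

    # intergenic indels
    indels: list[tuple[str, int, int, str]] = []  # scaffold, start, end, replacement
    for (sc, s, e), w in zip(gap_list, gap_weights):
        span = e - s
        n_ev = rng.binomial(span, config.indel_rate)
        for _ in range(n_ev):
            size = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # insertion
                pos = int(rng.integers(s, e))
                indels.append((sc, pos, pos, _random_seq(rng, size)))
            else:
                pos = int(rng.integers(s, max(s + 1, e - size)))
                indels.append((sc, pos, min(pos + size, e), ""))

    # collect edits per scaffold
    edits_by_sc: dict[str, list[tuple[int, int, str]]] = {
        sc: [] for sc in ancestor.sequences
    }
    flank = config.deletion_flank_bp
    for te_id in sorted(deleted):
        iv = te_by_id[te_id].interval
        s, e = iv.start, iv.end
        if flank:
            lo_cap, hi_cap = 0, len(ancestor.sequences[iv.scaffold_id])
            for fs, fe in bounds_by_sc.get(iv.scaffold_id, []):
                if fe <= s:
                    lo_cap = max(lo_cap, fe)
                if fs >= e:
                    hi_cap = min(hi_cap, fs)
            s = max(lo_cap, s - flank)
            e = min(hi_cap, e + flank)
        edits_by_sc[iv.scaffold_id].append((s, e, ""))
    for sc, pos, seq, _ in new_tes:
        edits_by_sc[sc].append((pos, pos, seq))
    for sc, s, e, repl in indels:
        edits_by_sc[sc].append((s, e, repl))

    sequences: dict[str, str] = {}
    applied: dict[str, list[tuple[int, int, int]]] = {}  # (start, end, cum. delta)
    kept_insertions: set[tuple[str, int, str]] = set()
    for sc, seq in ancestor.sequences.items():
        edits = sorted(edits_by_sc[sc], key=lambda x: (x[0], x[1]))
        cleaned = []
        last_end = -1
        for s, e, repl in edits:
            if s < last_end:
                if e <= last_end or repl:
                    continue  # colliding insertion/contained deletion: drop
                s = last_end  # trim an overlapping deletion
            cleaned.append((s, e, repl))
            if repl and s == e:
                kept_insertions.add((sc, s, repl))
            last_end = max(last_end, e, s)
        pieces = []
        pos = 0
        mapping = []
        delta = 0
        for s, e, repl in cleaned:
            pieces.append(seq[pos:s])
            pieces.append(repl)
            delta += len(repl) - (e - s)
            mapping.append((s, e, delta))
            pos = e
        pieces.append(seq[pos:])
        sequences[sc] = "".join(pieces)
        applied[sc] = mapping

    def _map_pos(sc: str, x: int) -> int:
        # an edit shifts x iff it ends before x, or is a deletion ending at x;
        # insertions at exactly x stay outside the feature (sampling keeps
        # insertion points away from feature boundaries)
        delta = 0
        for s, e, d in applied[sc]:
            if e < x or (e == x and e > s):
                delta = d
            elif s >= x:
                break
        return x + delta

    def map_interval(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(
            iv.scaffold_id,
            _map_pos(iv.scaffold_id, iv.start),
            _map_pos(iv.scaffold_id, iv.end),
            iv.strand,
        )

    genes = [
        GeneFeature(
            g.gene_id,
            map_interval(g.interval),
            [map_interval(c) for c in g.cds_intervals],
        )
        for g in ancestor.genes
    ]
    tes: list[TECopy] = []
    origin = dict(getattr(ancestor, "te_origin", {}))
    for t in ancestor.tes:
        if t.te_id in deleted:
            continue
        tes.append(
            TECopy(t.te_id, map_interval(t.interval), t.family_id, t.superfamily,
                   t.identity_to_consensus)
        )
    seen_ins: set[tuple[str, int]] = set()
    for sc, pos, seq, proto in new_tes:
        if (sc, pos, seq) not in kept_insertions or (sc, pos) in seen_ins:
            continue  # lost to an edit collision; stays unannotated
        seen_ins.add((sc, pos))
        new_start = _map_pos(sc, pos)
        tes.append(
            TECopy(
                proto.te_id,
                GenomicInterval(sc, new_start, new_start + len(seq), "+"),
                proto.family_id,
                proto.superfamily,
                100.0,
            )
        )
        origin[proto.te_id] = (proto.family_id, proto.cons_start)
        fate[proto.te_id] = proto.te_id

    # neutral substitutions, stop-free in CDS
    rate = config.substitution_rate_between_species / 2.0
    arrays = {
        sc: np.frombuffer(seq.encode(), np.uint8).copy()
        for sc, seq in sequences.items()
    }
    if rate > 0:
        for sc in sorted(arrays):
            arr = arrays[sc]
            before = arr.copy()
            hit = np.flatnonzero(rng.random(arr.shape[0]) < rate)
            if hit.size:
                codes = np.searchsorted(_ACGT, arr[hit])
                arr[hit] = _ACGT[(codes + rng.integers(1, 4, hit.size)) % 4]
            arrays[sc] = arr
            # revert substitutions that created premature stops
            for g in genes:
                if g.interval.scaffold_id != sc:
                    continue
                segs = [(c.start, c.end) for c in g.cds_intervals]
                cds = np.concatenate([arr[s:e] for s, e in segs])
                old = np.concatenate([before[s:e] for s, e in segs])
                n_codons = cds.shape[0] // 3
                flat = [i for s, e in segs for i in range(s, e)]
                for ci in range(n_codons - 1):
                    codon = bytes(cds[3 * ci : 3 * ci + 3]).decode()
                    if codon in _STOPS:
                        for k in range(3):
                            arr[flat[3 * ci + k]] = old[3 * ci + k]
    sequences = {sc: arrays[sc].tobytes().decode() for sc in arrays}

    # refresh identity-to-consensus against the recorded consensus window
    final_tes = []
    for t in tes:
        fam, cons_start = origin[t.te_id]
        window = library[fam][cons_start : cons_start + t.interval.length]
        copy_seq = sequences[t.interval.scaffold_id][t.interval.start : t.interval.end]
        final_tes.append(replace(t, identity_to_consensus=_hamming_identity(copy_seq, window)))

    genome = AnnotatedGenome(label, sequences, genes, final_tes)
    genome.te_origin = origin
    return genome, fate


def evolve_pair(
    ancestor: AnnotatedGenome,
    consensus_library: dict[str, str],
    config: SimulationConfig,
) -> tuple[AnnotatedGenome, AnnotatedGenome, TruthTable]:
    """Evolve two independent descendant lineages and record every TE's fate."""
    config.validate()
    index = GeneIndex(ancestor.genes)
    genic = {
        te.te_id: classify_te_location(te, index) != "intergenic"
        for te in ancestor.tes
    }
    genome_a, fate_a = _evolve_one(
        ancestor, consensus_library, config,
        np.random.default_rng([config.seed, 11]), "A", genic,
    )
    genome_b, fate_b = _evolve_one(
        ancestor, consensus_library, config,
        np.random.default_rng([config.seed, 22]), "B", genic,
    )
    rows = []
    for te in ancestor.tes:
        fa = fate_a[te.te_id]
        fb = fate_b[te.te_id]
        retained_a = fa != "deleted"
        retained_b = fb != "deleted"
        if retained_a and retained_b:
            call = "orthologous"
        elif retained_a or retained_b:
            # a young survivor is indistinguishable from a post-split insertion
            young = (te.identity_to_consensus or 0.0) >= 90.0
            call = "not_interrogated" if young else "non_orthologous"
        else:
            call = "not_interrogated"
        rows.append(TruthRow(te.te_id, fa, fb, call))
    for te_id in sorted(set(fate_a) - {t.te_id for t in ancestor.tes}):
        rows.append(TruthRow(te_id, te_id, "absent", "not_interrogated"))
    for te_id in sorted(set(fate_b) - {t.te_id for t in ancestor.tes}):
        rows.append(TruthRow(te_id, "absent", te_id, "not_interrogated"))
    return genome_a, genome_b, TruthTable(rows)


# ---------------------------------------------------------------------------
# Side tables (siRNA, methylation, expression, mobilome evidence)
# ---------------------------------------------------------------------------

def simulate_side_tables(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw siRNA, methylation, expression and mobilome-evidence tables.

    Group effects (orthologous/non-orthologous x genic/intergenic) are scaled
    by the ``*_contrast`` config fields; a contrast of 0 yields exchangeable
    groups, the null case.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 33])
    status = truth.status_by_te("a")
    index = GeneIndex(genome_a.genes)
    loc = {t.te_id: classify_te_location(t, index) for t in genome_a.tes}

    # --- siRNA: log-rpm means shifted per group --------------------------------
    base_mu = math.log(3.0)
    offsets = {
        ("orthologous", True): -1.2,
        ("non_orthologous", True): 0.3,
        ("orthologous", False): 0.8,
        ("non_orthologous", False): 0.9,
    }
    sirna_rows = []
    for t in genome_a.tes:
        genic = loc[t.te_id] != "intergenic"
        st = status.get(t.te_id, "not_interrogated")
        off = offsets.get((st, genic), 0.0) * config.sirna_contrast
        rpm = float(rng.lognormal(base_mu + off, 1.0))
        cov = float(rng.beta(2.0, 2.0))
        sirna_rows.append((t.te_id, round(rpm, 4), round(cov, 4)))
    sirna = pd.DataFrame(sirna_rows, columns=["te_id", "reads_per_million", "covered_fraction"])

    # --- methylation: per-cytosine rates for 4 conditions ----------------------
    group_mean = {
        ("orthologous", True): 0.04,
        ("non_orthologous", True): 0.23,
        ("orthologous", False): 0.18,
        ("non_orthologous", False): 0.32,
    }
    overall = 0.18
    meth_rows = []
    conditions = ["shoot", "root", "cold4C", "warm23C"]
    for t in genome_a.tes:
        genic = loc[t.te_id] != "intergenic"
        st = status.get(t.te_id, "not_interrogated")
        m = overall + config.meth_contrast * (
            group_mean.get((st, genic), overall) - overall
        )
        seq = genome_a.sequence_of(t.interval)
        c_positions = [i for i, b in enumerate(seq) if b == "C"]
        for i in c_positions:
            if rng.random() > config.meth_site_coverage:
                continue
            pos = t.interval.start + i
            ctx = seq[i : i + 3]
            if ctx.startswith("CG"):
                context = "CG"
            elif len(ctx) == 3 and ctx[2] == "G":
                context = "CHG"
            else:
                context = "CHH"
            if rng.random() < m:
                rates = rng.beta(5.0, 2.0, 4)
            else:
                rates = rng.beta(1.0, 30.0, 4)
            meth_rows.append(
                (t.interval.scaffold_id, pos, context, *np.round(rates, 4))
            )
    methylation = pd.DataFrame(
        meth_rows, columns=["scaffold", "position", "context"] + conditions
    )

    # --- expression: per-gene counts, TE-status-dependent means ----------------
    hosts: dict[str, str] = {}
    for t in genome_a.tes:
        if loc[t.te_id] == "intergenic":
            continue
        st = status.get(t.te_id, "not_interrogated")
        for g in index.overlapping_genes(t.interval):
            prev = hosts.get(g.gene_id)
            if st == "orthologous" or prev is None:
                hosts[g.gene_id] = st
    expr_rows = []
    for g in genome_a.genes:
        length = sum(c.length for c in g.cds_intervals)
        mu = 200.0
        if hosts.get(g.gene_id) == "orthologous":
            mu *= math.exp(-0.7 * config.expression_contrast)
        n_disp = 5.0
        count = int(rng.negative_binomial(n_disp, n_disp / (n_disp + mu)))
        expr_rows.append((g.gene_id, length, count))
    expression = pd.DataFrame(expr_rows, columns=["transcript_id", "length", "count"])

    # --- mobilome evidence ------------------------------------------------------
    accessions = [f"acc{i:02d}" for i in range(1, config.n_accessions + 1)]
    sfs = sorted(config.superfamily_weights)
    sf_w = np.array([config.superfamily_weights[s] for s in sfs])
    sf_w = sf_w / sf_w.sum()
    scaffolds = sorted(genome_a.sequences)
    mob_rows = []
    truth_sites = []
    for i in range(config.n_true_insertions):
        sc = scaffolds[int(rng.integers(0, len(scaffolds)))]
        pos = int(rng.integers(1000, len(genome_a.sequences[sc]) - 1000))
        family = sfs[int(rng.choice(len(sfs), p=sf_w))]
        carriers_n = 1 + int(rng.binomial(config.n_accessions - 1, 0.3))
        carriers = list(rng.choice(config.n_accessions, carriers_n, replace=False))
        truth_sites.append((sc, pos, family, sorted(int(c) for c in carriers)))
        for rank, ci in enumerate(sorted(int(c) for c in carriers)):
            if rank == 0:
                disc = 6 + int(rng.poisson(4.0))
                split = 5 + int(rng.poisson(3.0))
            else:
                total = config.mobilome_min_carrier_support + int(rng.poisson(3.0))
                split = int(rng.integers(0, total + 1))
                disc = total - split
            mob_rows.append(
                (accessions[ci], sc, pos, family, disc, split, bool(rng.random() < 0.9))
            )
    for i in range(config.n_noise_sites):
        sc = scaffolds[int(rng.integers(0, len(scaffolds)))]
        pos = int(rng.integers(1000, len(genome_a.sequences[sc]) - 1000))
        family = sfs[int(rng.choice(len(sfs), p=sf_w))]
        for ci in rng.choice(config.n_accessions, int(rng.integers(1, 4)), replace=False):
            mob_rows.append(
                (accessions[int(ci)], sc, pos, family, int(rng.integers(0, 2)), 0,
                 bool(rng.random() < 0.1))
            )
    mobilome = pd.DataFrame(
        mob_rows,
        columns=[
            "accession_id", "scaffold", "position", "te_family",
            "discordant_reads", "split_reads", "tsd_present",
        ],
    )
    mobilome.attrs["truth_sites"] = truth_sites
    return sirna, methylation, expression, mobilome
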