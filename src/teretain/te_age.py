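"""TE age from identity to the family consensus.

The percent identity of a copy to its family consensus is the classical proxy
for relative insertion age: copies start identical to their source element and
diverge neutrally afterwards.  Copies are split into "old" and "young" classes
at a 90% identity threshold, the antimode of the strongly bimodal identity
distribution these genomes show.  The boundary itself (identity exactly 90)
is classified young; the threshold is exposed everywhere as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from numba import njit

from . import _align
from ._align import AlignParams
from .formats import SUPERFAMILIES, AnnotatedGenome

__all__ = [
    "AgeClassification",
    "AgeHistogram",
    "identity_to_consensus",
    "classify_age",
    "age_summary",
    "young_fraction_percent",
    "fraction_percent",
    "estimate_te_content_from_reads",
]

OLD, YOUNG = "old", "young"


def _identity_aligner() -> Align.PairwiseAligner:
    # fragment-vs-consensus semi-global: end gaps on the consensus are free
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aligner.end_deletion_score = 0.0  # consensus overhangs align to nothing, free
    return aligner


_ALIGNER = _identity_aligner()


def identity_to_consensus(copy_sequence: str, consensus_sequence: str) -> float:
    """Percent identity of a TE copy to its family consensus.

    Semi-global alignment (free end gaps on the consensus, so the copy may
    match any stretch of it); identity is matches over the columns in which
    the copy contributes a base, i.e. matches / len(copy) * 100.
    """
    if not copy_sequence or not consensus_sequence:
        raise ValueError("identity_to_consensus requires non-empty sequences")
    copy_sequence = copy_sequence.upper()
    consensus_sequence = consensus_sequence.upper()
    alignment = _ALIGNER.align(consensus_sequence, copy_sequence)[0]
    matches = 0
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        t = consensus_sequence[ts:te]
        q = copy_sequence[qs:qe]
        matches += sum(a == b for a, b in zip(t, q))
    return 100.0 * matches / len(copy_sequence)


def classify_age(identity: float, threshold: float = 90.0) -> str:
    """'young' iff identity >= threshold, else 'old'."""
    if not (0.0 <= identity <= 100.0):
        raise ValueError(f"identity out of range: {identity}")
    return YOUNG if identity >= threshold else OLD


@dataclass(frozen=True)
class AgeClassification:
    te_id: str
    identity: float
    age_class: str


@dataclass
class AgeHistogram:
    """1-point identity histogram, overall and per superfamily."""

    bin_edges: np.ndarray               # 101 edges: 0..100
    counts: np.ndarray                  # length 100
    counts_by_superfamily: dict[str, np.ndarray]
    total: int
    young: int
    threshold: float

    @property
    def young_fraction_percent(self) -> float:
        return young_fraction_percent(self.young, self.total)

    def antimode(self, lo: float = 70.0, hi: float = 100.0) -> float:
        """Identity of the emptiest bin between the two modes (valley)."""
        edges = self.bin_edges
        sel = (edges[:-1] >= lo) & (edges[:-1] < hi)
        idx = np.flatnonzero(sel)
        valley = idx[np.argmin(self.counts[idx])]
        return float(edges[valley] + 0.5)


def fraction_percent(part: float, total: float, ndigits: int = 1) -> float:
    """A share as a percent, rounded the way summary tables print it."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, ndigits)


def young_fraction_percent(young: int, total: int) -> float:
    """Young share as a percent, reported to one decimal (e.g. 30.9)."""
    return fraction_percent(young, total)


def age_summary(
    genome: AnnotatedGenome | list, threshold: float = 90.0
) -> tuple[list[AgeClassification], AgeHistogram]:
    """Classify every TE with a recorded identity and histogram the ages."""
    tes = genome.tes if isinstance(genome, AnnotatedGenome) else list(genome)
    tes = [t for t in tes if t.identity_to_consensus is not None]
    if not tes:
        edges = np.arange(101, dtype=float)
        empty = AgeHistogram(edges, np.zeros(100, int), {}, 0, 0, threshold)
        return [], empty
    classes = [
        AgeClassification(t.te_id, t.identity_to_consensus,
                          classify_age(t.identity_to_consensus, threshold))
        for t in tes
    ]
    edges = np.arange(101, dtype=float)
    idents = np.array([t.identity_to_consensus for t in tes])
    counts, _ = np.histogram(np.clip(idents, 0, 99.999), bins=edges)
    by_sf: dict[str, np.ndarray] = {}
    for sf in SUPERFAMILIES:
        vals = [t.identity_to_consensus for t in tes if t.superfamily == sf]
        if vals:
            by_sf[sf], _ = np.histogram(np.clip(vals, 0, 99.999), bins=edges)
    young = sum(c.age_class == YOUNG for c in classes)
    return classes, AgeHistogram(edges, counts, by_sf, len(tes), young, threshold)


# ---------------------------------------------------------------------------
# Assembly-free TE content from reads
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_read(q, s, s_sorted_vals, s_order, k, match, mismatch,
               min_score, low_bar, xdrop):  # pragma: no cover - jit
    """Seeded ungapped X-drop scan of a read against the indexed library.

    Returns (verdict, best_seed_pos): verdict 1 = ungapped score already
    reaches ``min_score`` (the gapped score can only be higher), 0 = no seed
    reached ``low_bar``, 2 = borderline, gapped DP needed around the seed.
    """
    qcodes = _align._kmer_codes(q, k)
    best = 0
    best_spos = -1
    m = q.shape[0]
    n = s.shape[0]
    for qpos in range(qcodes.shape[0]):
        code = qcodes[qpos]
        if code < 0:
            continue
        lo = np.searchsorted(s_sorted_vals, code, side="left")
        hi = np.searchsorted(s_sorted_vals, code, side="right")
        for idx in range(lo, hi):
            spos = s_order[idx]
            score = k * match
            # extend right
            run = score
            peak = score
            i = qpos + k
            j = spos + k
            while i < m and j < n:
                run += match if q[i] == s[j] else mismatch
                if run > peak:
                    peak = run
                if peak - run > xdrop:
                    break
                i += 1
                j += 1
            score = peak
            # extend left
            run = score
            peak = score
            i = qpos - 1
            j = spos - 1
            while i >= 0 and j >= 0:
                run += match if q[i] == s[j] else mismatch
                if run > peak:
                    peak = run
                if peak - run > xdrop:
                    break
                i -= 1
                j -= 1
            if peak >= min_score:
                return 1, spos
            if peak > best:
                best = peak
                best_spos = spos
    if best >= low_bar:
        return 2, best_spos
    return 0, -1


def estimate_te_content_from_reads(
    reads: list[str],
    consensus_library: dict[str, str],
    min_score: int = 50,
    seed_k: int = 9,
    params: AlignParams | None = None,
) -> float:
    """Fraction of reads with a local-alignment hit to the consensus library.

    The library is concatenated (N-separated) and indexed by exact k-mers.
    Seeds are extended ungapped with an X-drop; a read whose extension
    reaches ``min_score`` maps outright, borderline seeds are re-scored with
    the affine-gap local DP, and a read with no seeded extension above half
    the threshold does not map.
    """
    if not reads:
        raise ValueError("no reads supplied")
    if not consensus_library:
        raise ValueError("empty consensus library")
    p = params or AlignParams()
    subject = ("N" * 25).join(consensus_library[name] for name in consensus_library)
    s = _align._encode(subject)
    s_sorted_vals, s_order = _align._subject_index(s, seed_k)
    low_bar = min_score // 2
    n_mapped = 0
    for read in reads:
        mapped = False
        for seq in (read.upper(), _align.revcomp(read.upper())):
            q = _align._encode(seq)
            verdict, spos = _scan_read(
                q, s, s_sorted_vals, s_order, seed_k, p.match, p.mismatch,
                min_score, low_bar, 20,
            )
            if verdict == 1:
                mapped = True
            elif verdict == 2:
                lo = max(0, int(spos) - q.shape[0] - 50)
                hi = min(s.shape[0], int(spos) + 2 * q.shape[0] + 50)
                res = _align._align_arrays(q, s[lo:hi], p)
                mapped = bool(res is not None and res[0] >= min_score)
            if mapped:
                break
        n_mapped += mapped
    return n_mapped / len(reads)
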