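"""Nucleotide local alignment: banded seed-and-extend over an affine-gap
Smith-Waterman core, with Karlin-Altschul E-values.

Small problems (query x subject below ``exact_max`` cells) are solved by the
full dynamic program, so scores there are exact; larger searches are seeded
with exact k-mer matches and each seeded diagonal cluster is extended by the
same dynamic program on a subject window.  Gap costs follow the BLAST
convention: a gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = ["AlignParams", "AlignmentHit", "local_align", "revcomp"]

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and search parameters (blastn-like defaults)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5      # gap existence cost (positive)
    gap_extend: int = 2    # per-residue cost (positive)
    k: int = 11            # seed word size
    exact_max: int = 500_000   # cells below which the full DP is run
    band: int = 32         # diagonal tolerance when clustering seeds
    window_pad: int = 64   # extra subject context around a seed cluster
    max_hits: int = 5
    e_report: float = 10.0  # hits with larger E-value are dropped
    karlin_k: float = 0.41  # Karlin-Altschul K for this scoring scheme

    @property
    def karlin_lambda(self) -> float:
        return _ungapped_lambda(self.match, self.mismatch)


@lru_cache(maxsize=None)
def _ungapped_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda s_ij) = 1 for uniform base composition."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass(frozen=True)
class AlignmentHit:
    """One gapped local alignment between a query and a subject sequence.

    Coordinates are 0-based half-open on the forward strands of both input
    sequences; ``strand`` is '-' when the reverse complement of the query
    produced the hit.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: int
    identity: float       # percent matches over alignment columns
    e_value: float
    columns: int
    matches: int


@njit(cache=True)
def _gotoh(q, s, match, mismatch, open_total, extend):  # pragma: no cover - jit
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int32)
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - extend
            t = H[i, j - 1] - open_total
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - extend
            t = H[i - 1, j] - open_total
            if t > f:
                f = t
            F[i, j] = f
            sub = match if qi == s[j - 1] else mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, E, F


@njit(cache=True)
def _traceback(q, s, H, E, F, bi, bj, match, mismatch, open_total, extend):  # pragma: no cover - jit
    i = bi
    j = bj
    columns = 0
    matches = 0
    state = 0  # 0=H, 1=E (gap consuming subject), 2=F (gap consuming query)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            sub = match if q[i - 1] == s[j - 1] else mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub:
                columns += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] - open_total:
                j -= 1
                state = 0
            else:
                j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] - open_total:
                i -= 1
                state = 0
            else:
                i -= 1
    return i, j, columns, matches


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def _align_arrays(q: np.ndarray, s: np.ndarray, p: AlignParams):
    """Exact local DP on encoded arrays; returns (score, qs, qe, ss, se, cols, matches)."""
    open_total = p.gap_open + p.gap_extend
    score, bi, bj, H, E, F = _gotoh(q, s, p.match, p.mismatch, open_total, p.gap_extend)
    if score <= 0:
        return None
    i0, j0, cols, matches = _traceback(
        q, s, H, E, F, bi, bj, p.match, p.mismatch, open_total, p.gap_extend
    )
    return int(score), i0, bi, j0, bj, int(cols), int(matches)


def _e_value(score: int, m: int, n: int, p: AlignParams) -> float:
    return p.karlin_k * m * n * math.exp(-p.karlin_lambda * score)


@njit(cache=True)
def _kmer_codes(arr, k):  # pragma: no cover - jit
    """Rolling 2-bit k-mer codes; -1 where the window has a non-ACGT base."""
    n = arr.shape[0]
    out = np.full(max(0, n - k + 1), -1, dtype=np.int64)
    val = np.int64(0)
    run = 0
    mask = np.int64((1 << (2 * k)) - 1)
    for i in range(n):
        b = arr[i]
        if b == 65:
            c = 0
        elif b == 67:
            c = 1
        elif b == 71:
            c = 2
        elif b == 84:
            c = 3
        else:
            run = 0
            val = 0
            continue
        val = ((val << 2) | c) & mask
        run += 1
        if run >= k:
            out[i - k + 1] = val
    return out


@njit(cache=True)
def _match_seeds(qcodes, s_sorted_vals, s_order):  # pragma: no cover - jit
    """(diagonal, subject_pos) pairs for every exact k-mer shared with the
    subject (whose codes are pre-sorted)."""
    diags = []
    sposs = []
    for qpos in range(qcodes.shape[0]):
        code = qcodes[qpos]
        if code < 0:
            continue
        lo = np.searchsorted(s_sorted_vals, code, side="left")
        hi = np.searchsorted(s_sorted_vals, code, side="right")
        for idx in range(lo, hi):
            spos = s_order[idx]
            diags.append(spos - qpos)
            sposs.append(spos)
    return np.array(diags, dtype=np.int64), np.array(sposs, dtype=np.int64)


def _seed_clusters(q: np.ndarray, s: np.ndarray, p: AlignParams, subject_index=None):
    """Exact k-mer seeds grouped into diagonal clusters -> subject windows."""
    k = p.k
    if q.shape[0] < k or s.shape[0] < k:
        return []
    if subject_index is None:
        subject_index = _subject_index(s, k)
    s_sorted_vals, s_order = subject_index
    qcodes = _kmer_codes(q, k)
    diags, sposs = _match_seeds(qcodes, s_sorted_vals, s_order)
    if diags.shape[0] == 0:
        return []
    seeds = sorted(zip(diags.tolist(), sposs.tolist()))
    qlen = q.shape[0]
    clusters: list[tuple[int, int]] = []  # subject (lo, hi) windows
    cur_d, cur_lo, cur_hi = seeds[0][0], seeds[0][1], seeds[0][1]
    for d, spos in seeds[1:]:
        if d - cur_d <= p.band and spos - cur_hi <= qlen:
            cur_hi = max(cur_hi, spos)
            cur_d = d
        else:
            clusters.append((cur_lo, cur_hi))
            cur_d, cur_lo, cur_hi = d, spos, spos
    clusters.append((cur_lo, cur_hi))
    pad = qlen + p.window_pad
    windows = []
    for lo, hi in clusters:
        windows.append((max(0, lo - pad), min(s.shape[0], hi + p.k + pad)))
    # merge overlapping windows
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _subject_index(s: np.ndarray, k: int):
    codes = _kmer_codes(s, k)
    order = np.argsort(codes, kind="stable").astype(np.int64)
    return codes[order], order


def _hits_one_strand(
    q: np.ndarray, s: np.ndarray, strand: str, qlen_orig: int, m: int, n: int,
    p: AlignParams, subject_index=None,
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []

    def _emit(res, offset: int) -> None:
        score, qs, qe, ss, se, cols, matches = res
        e = _e_value(score, m, n, p)
        if e > p.e_report:
            return
        if strand == "-":
            q0, q1 = qlen_orig - qe, qlen_orig - qs
        else:
            q0, q1 = qs, qe
        hits.append(
            AlignmentHit(
                q0, q1, offset + ss, offset + se, strand, score,
                100.0 * matches / cols if cols else 0.0, e, cols, matches,
            )
        )

    if q.shape[0] * s.shape[0] <= p.exact_max:
        sub = s.copy()
        for _ in range(p.max_hits):
            res = _align_arrays(q, sub, p)
            if res is None:
                break
            _emit(res, 0)
            if _e_value(res[0], m, n, p) > p.e_report:
                break
            sub[res[3] : res[4]] = 1  # mask matched subject span, look again
        return hits
    for lo, hi in _seed_clusters(q, s, p, subject_index):
        res = _align_arrays(q, s[lo:hi], p)
        if res is not None:
            _emit(res, lo)
    return hits


def local_align(query: str, subject: str, params: AlignParams | None = None) -> list[AlignmentHit]:
    """Gapped local alignment of ``query`` against both strands of ``subject``.

    Returns hits with E-value <= ``params.e_report`` sorted by ascending
    E-value (ties broken by descending score and subject position).  Empty
    list when nothing aligns.
    """
    p = params or AlignParams()
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    m, n = len(query), len(subject)
    s = _encode(subject)
    subject_index = None
    if m * n > p.exact_max and min(m, n) >= p.k:
        subject_index = _subject_index(s, p.k)
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        hits.extend(_hits_one_strand(_encode(qseq), s, strand, m, m, n, p, subject_index))
    # drop duplicate/contained subject spans, best first
    hits.sort(key=lambda h: (h.e_value, -h.score, h.subject_start, h.strand))
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            ov = min(h.subject_end, g.subject_end) - max(h.subject_start, g.subject_start)
            if ov > 0.5 * (h.subject_end - h.subject_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
        if len(kept) >= p.max_hits:
            break
    return kept
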