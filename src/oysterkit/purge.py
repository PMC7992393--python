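"""Iterative, length-ordered all-versus-all haplotig purging.

Highly heterozygous diploid genomes assemble both haplotypes of many loci
as separate contigs; the redundant copies (haplotigs) must be removed to
obtain a pseudo-haploid reference.  The procedure here takes contigs in
decreasing length order, maps all remaining contigs against the current
longest (the reference), removes any contig that maps over at least 30%
of its own length and is longer than 10 kb, then retires the reference
and iterates on the rest.  An externally produced keep-list (e.g. from a
coverage-based purger) can be intersected with the result.

Mapping is approximate and self-contained: canonical minimizers (k=15,
w=10) are matched per 500-bp query window; a window counts as covered
when at least `min_hits` of its minimizers occur in the target.  Repeat
intervals can be soft-masked so repeat-mediated matches are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_core import Feature, SeqRecord

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_MIX = np.uint64(0x9E3779B97F4A7C15)
_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class MappingHit:
    query_id: str
    target_id: str
    query_covered_bp: int
    query_covered_frac: float


@dataclass
class Removal:
    contig_id: str
    reason: str  # "haplotig_map" | "external_only"
    evidence: MappingHit | None = None


@dataclass
class PurgeResult:
    kept_ids: set[str]
    removed: list[Removal]

    @property
    def removed_ids(self) -> set[str]:
        return {r.contig_id for r in self.removed}


def _hash_codes(codes: np.ndarray) -> np.ndarray:
    """Invertible 64-bit mix so minimizer choice is not lexicographic."""
    h = codes * _MIX
    h ^= h >> np.uint64(29)
    h *= np.uint64(0xBF58476D1CE4E5B9)
    h ^= h >> np.uint64(32)
    return h


def _canonical_kmer_hashes(seq: str, k: int, mask: np.ndarray | None) -> np.ndarray:
    """Hash of the canonical k-mer at every position (sentinel where the
    k-mer touches N or a masked base)."""
    codes = _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    m = len(codes) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        chunk = codes[j : j + m]
        bad |= chunk == 4
        c = (chunk & 3).astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | c
        rev |= (np.uint64(3) - c) << np.uint64(2 * j)
    if mask is not None:
        cum = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
        bad |= (cum[k:] - cum[:-k]) > 0
    h = _hash_codes(np.minimum(fwd, rev))
    h[bad] = _SENTINEL
    return h


@dataclass
class ContigIndex:
    positions: np.ndarray  # minimizer positions
    hashes: np.ndarray  # hashes at those positions
    sorted_hashes: np.ndarray  # unique sorted, for membership queries
    length: int


def build_minimizer_index(
    contigs: Sequence[SeqRecord],
    k: int = 15,
    w: int = 10,
    repeat_mask: Sequence[Feature] | None = None,
) -> dict[str, ContigIndex]:
    """(minimizer hash, position) sets per contig; deterministic for fixed
    (k, w).  Contigs too short for any window keep whatever minimizers
    exist (possibly none)."""
    masks: dict[str, np.ndarray] = {}
    if repeat_mask:
        for f in repeat_mask:
            masks.setdefault(f.seq_id, None)
        for rec in contigs:
            if rec.id in masks:
                masks[rec.id] = np.zeros(len(rec.seq), dtype=bool)
        for f in repeat_mask:
            if f.seq_id in masks and masks[f.seq_id] is not None:
                masks[f.seq_id][f.start : min(f.end, len(masks[f.seq_id]))] = True

    index: dict[str, ContigIndex] = {}
    for rec in contigs:
        h = _canonical_kmer_hashes(rec.seq, k, masks.get(rec.id))
        if len(h) == 0:
            index[rec.id] = ContigIndex(
                np.empty(0, np.int64), np.empty(0, np.uint64),
                np.empty(0, np.uint64), len(rec.seq),
            )
            continue
        if len(h) <= w:
            pos = np.array([int(np.argmin(h))])
        else:
            win = np.lib.stride_tricks.sliding_window_view(h, w)
            pos = np.unique(np.arange(len(h) - w + 1) + np.argmin(win, axis=1))
        hp = h[pos]
        keep = hp != _SENTINEL
        pos, hp = pos[keep], hp[keep]
        index[rec.id] = ContigIndex(pos, hp, np.unique(hp), len(rec.seq))
    return index


def map_contig(
    query_id: str,
    index: dict[str, ContigIndex],
    target_ids: Sequence[str],
    window: int = 500,
    min_hits: int = 10,
) -> dict[str, MappingHit]:
    """Best window-coverage hit of `query_id` against each target.

    The covered fraction is the union length of 500-bp tiling query
    windows in which >= `min_hits` minimizers match the same target,
    divided by the full query length.
    """
    q = index[query_id]
    out: dict[str, MappingHit] = {}
    if q.length == 0:
        return out
    n_win = (q.length + window - 1) // window
    win_idx = q.positions // window
    win_len = np.full(n_win, window, dtype=np.int64)
    win_len[-1] = q.length - (n_win - 1) * window
    for tid in target_ids:
        if tid == query_id:
            continue
        t = index[tid]
        if len(q.hashes) == 0 or len(t.sorted_hashes) == 0:
            out[tid] = MappingHit(query_id, tid, 0, 0.0)
            continue
        loc = np.searchsorted(t.sorted_hashes, q.hashes)
        loc[loc >= len(t.sorted_hashes)] = len(t.sorted_hashes) - 1
        matched = t.sorted_hashes[loc] == q.hashes
        hits = np.bincount(win_idx[matched], minlength=n_win)
        covered = int(np.sum(win_len[hits >= min_hits]))
        out[tid] = MappingHit(query_id, tid, covered, covered / q.length)
    return out


def iterative_purge(
    contigs: Sequence[SeqRecord],
    repeat_mask: Sequence[Feature] | None = None,
    min_len: int = 10_000,
    min_frac: float = 0.30,
    k: int = 15,
    w: int = 10,
    window: int = 500,
    min_hits: int = 10,
    min_match_span: int | None = None,
) -> PurgeResult:
    """Length-ordered iterative haplotig removal.

    Contigs are sorted by decreasing length (ties by id).  The longest
    unprocessed contig becomes the reference; every other unprocessed
    contig mapping >= `min_frac` of its length to it AND longer than
    `min_len` is removed with the mapping recorded as evidence.  The
    reference is kept, removed contigs leave the pool, and the procedure
    repeats until the pool is empty.  Contigs of length <= `min_len` are
    never removed by this rule.  `min_match_span`, when set, additionally
    requires the covered length itself to exceed that many bp.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    index = build_minimizer_index(contigs, k=k, w=w, repeat_mask=repeat_mask)
    lengths = {rec.id: len(rec.seq) for rec in contigs}
    pool = sorted(lengths, key=lambda cid: (-lengths[cid], cid))
    kept: set[str] = set()
    removed: list[Removal] = []
    while pool:
        ref = pool[0]
        others = pool[1:]
        dropped: set[str] = set()
        if others:
            hits = {
                tid: hit
                for tid, hit in (
                    (o, map_contig(o, index, [ref], window=window, min_hits=min_hits)[ref])
                    for o in others
                )
            }
            for o in others:
                hit = hits[o]
                if hit.query_covered_frac >= min_frac and lengths[o] > min_len:
                    if min_match_span is not None and hit.query_covered_bp <= min_match_span:
                        continue
                    removed.append(Removal(o, "haplotig_map", hit))
                    dropped.add(o)
        kept.add(ref)
        pool = [c for c in others if c not in dropped]
    return PurgeResult(kept, removed)


def intersect_keep_lists(
    kept_a: set[str], kept_b: set[str], universe: set[str]
) -> PurgeResult:
    """Keep contigs present in both independently curated lists; contigs
    missing from either list are reported removed with reason
    `external_only`."""
    for name, s in (("A", kept_a), ("B", kept_b)):
        extra = s - universe
        if extra:
            raise ValueError(f"keep-list {name} ids not in universe: {sorted(extra)[:5]}")
    kept = kept_a & kept_b
    if not kept:
        warnings.warn("keep-list intersection is empty", stacklevel=2)
    removed = [Removal(cid, "external_only") for cid in sorted(universe - kept)]
    return PurgeResult(kept, removed)
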