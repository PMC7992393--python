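"""Substructure screening and Helitron/Helentron classification.

Helentrons are a structural variant of Helitrons distinguished by
sub-terminal inverted repeats (subTIRs) and, in their non-autonomous HINE
form, by a 5'-end inverted repeat complementary to the subTIR and a 5'
microsatellite.  This module screens detected candidates for those three
substructures inside fixed terminal windows and classifies each element:

* no subTIR                         -> ``helitron``
* subTIR plus 5' IR or microsat     -> ``helentron_like``
* subTIR only                       -> ``intermediate``

Search thresholds (window 50 bp, subTIR >= 12 bp with 0 mismatches) are
this implementation's documented defaults, set so that random terminal
sequence produces matches at a negligible rate; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .heliscan import HelitronCandidate
from .io_core import revcomp

CLASSES = ("helitron", "helentron_like", "intermediate")


@dataclass(frozen=True)
class SubTIR:
    pos5: int  # start of the 5' copy (element-relative)
    pos3: int  # start of the 3' copy
    length: int
    mismatches: int


@dataclass(frozen=True)
class IR5:
    pos: int
    length: int


@dataclass(frozen=True)
class Microsat:
    pos: int
    unit: str
    copies: int

    @property
    def span(self) -> int:
        return len(self.unit) * self.copies


@dataclass
class SubstructureReport:
    candidate_index: int
    subtir: SubTIR | None
    ir5: IR5 | None
    microsat: Microsat | None
    klass: str


def find_subtir(
    element_seq: str,
    terminal_window: int = 50,
    min_len: int = 12,
    max_mismatch: int = 0,
) -> SubTIR | None:
    """Longest inverted-repeat pair between the two terminal windows.

    The 5' copy must lie within the first `terminal_window` bp and the 3'
    copy (its reverse complement up to `max_mismatch`) within the last
    `terminal_window` bp; ties are broken toward the termini.
    """
    L = len(element_seq)
    if L < 2 * terminal_window:
        return None
    w5 = element_seq[:terminal_window]
    w3rc = revcomp(element_seq[L - terminal_window :])
    W = terminal_window
    best: tuple[int, int, int, int] | None = None  # (len, -closeness, a, b_rc)
    # diagonals of the w5 x w3rc match matrix; a - b = d
    for d in range(-(W - min_len), W - min_len + 1):
        a0 = max(0, d)
        b0 = max(0, -d)
        run = min(W - a0, W - b0)
        if run < min_len:
            continue
        # two-pointer longest stretch with <= max_mismatch mismatches
        mism_pos: list[int] = []
        left = 0
        for right in range(run):
            if w5[a0 + right] != w3rc[b0 + right]:
                mism_pos.append(right)
                if len(mism_pos) > max_mismatch:
                    left = mism_pos.pop(0) + 1
            span = right - left + 1
            if span >= min_len:
                a = a0 + left
                b_rc = b0 + left
                # pos3 of the 3' copy in element coordinates
                pos3 = L - terminal_window + (W - (b_rc + span))
                closeness = a + (L - (pos3 + span))
                mism = sum(
                    1
                    for t in range(span)
                    if w5[a + t] != w3rc[b_rc + t]
                )
                cand = (span, -closeness, -a, mism)
                if best is None or cand[:2] > best[0][:2]:
                    best = (cand, (a, pos3, span, mism))
    if best is None:
        return None
    a, pos3, span, mism = best[1]
    return SubTIR(a, pos3, span, mism)


def find_5prime_ir(
    element_seq: str,
    subtir: SubTIR,
    terminal_window: int = 50,
    max_mismatch: int = 0,
) -> IR5 | None:
    """A match to the reverse complement of the subTIR's 5' copy, inside
    the first terminal window and non-overlapping with that copy."""
    if subtir is None:
        raise ValueError("find_5prime_ir requires a subTIR")
    s5 = element_seq[subtir.pos5 : subtir.pos5 + subtir.length]
    target = revcomp(s5)
    L = len(target)
    w5 = element_seq[:terminal_window]
    best: IR5 | None = None
    best_mism = max_mismatch + 1
    for a in range(0, terminal_window - L + 1):
        if a < subtir.pos5 + subtir.length and subtir.pos5 < a + L:
            continue  # overlaps the subTIR's 5' copy
        mism = sum(1 for t in range(L) if w5[a + t] != target[t])
        if mism <= max_mismatch and mism < best_mism:
            best, best_mism = IR5(a, L), mism
    return best


def find_microsat(
    element_seq: str,
    window: int = 50,
    unit_range: tuple[int, int] = (1, 6),
    min_copies: int = 3,
    min_span: int = 9,
    homopolymer_min_span: int = 9,
) -> Microsat | None:
    """Longest perfect tandem run in the 5' window.

    Unit length within `unit_range`, at least `min_copies` complete
    copies, total span at least `min_span` (homopolymers: at least
    `homopolymer_min_span`).  Ties prefer the smaller unit, then the
    leftmost run.
    """
    w = element_seq[: min(window, len(element_seq))]
    n = len(w)
    best: Microsat | None = None
    for u in range(unit_range[0], unit_range[1] + 1):
        a = 0
        while a + u <= n:
            # extend a perfect run of period u starting at a
            end = a + u
            while end < n and w[end] == w[end - u]:
                end += 1
            copies = (end - a) // u
            span = copies * u
            need = homopolymer_min_span if u == 1 else min_span
            if copies >= min_copies and span >= need:
                cand = Microsat(a, w[a : a + u], copies)
                if (
                    best is None
                    or cand.span > best.span
                    or (cand.span == best.span and (u, a) < (len(best.unit), best.pos))
                ):
                    best = cand
            a = a + 1 if copies < 2 else end - u + 1
    return best


def classify(
    has_subtir: bool, has_ir5: bool, has_microsat: bool
) -> str:
    """Total classification over the three substructure flags."""
    if not has_subtir:
        return "helitron"
    if has_ir5 or has_microsat:
        return "helentron_like"
    return "intermediate"


def analyze_candidate(
    candidate: HelitronCandidate,
    forward_seq: str,
    index: int = 0,
    terminal_window: int = 50,
    min_subtir: int = 12,
    max_mismatch: int = 0,
) -> SubstructureReport:
    """Screen one candidate and fill its substructure flags and class."""
    elem = candidate.element_seq(forward_seq)
    subtir = (
        find_subtir(elem, terminal_window, min_subtir, max_mismatch)
        if len(elem) >= 2 * terminal_window
        else None
    )
    ir5 = (
        find_5prime_ir(elem, subtir, terminal_window, max_mismatch)
        if subtir is not None
        else None
    )
    ms = find_microsat(elem, window=terminal_window)
    klass = classify(subtir is not None, ir5 is not None, ms is not None)
    candidate.has_subtir = subtir is not None
    candidate.has_5prime_ir = ir5 is not None
    candidate.has_microsat = ms is not None
    candidate.klass = klass
    return SubstructureReport(index, subtir, ir5, ms, klass)
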