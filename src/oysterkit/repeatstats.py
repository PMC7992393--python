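"""Family clustering, capture screen, and genomic density statistics.

Helitron families are recognized by conserved 3' termini: the last 30 bp
of each element (including the terminal CTAG) are clustered greedily
against family centroids at a pairwise-identity floor of 0.80, identity
being matching alignment columns over total alignment columns of a
global alignment (match +1, mismatch -1, gap -2, end gaps penalized).
Gene-fragment capture is screened by six-frame translation and local
protein alignment (BLOSUM62, affine gaps); an alignment longer than 50
residues at >= 85% identity is a match.

Window statistics count each feature once, in the 100-kb window holding
the larger share of its length (ties toward the lower-coordinate
window).  Densities are correlated with the Pearson product-moment
coefficient (Spearman available); element density per genome is the
number of conserved 3' ends divided by genome size in Mb; a chromosome
is enriched when its density exceeds the across-chromosome mean by more
than one population SD.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy import stats as _stats

from .io_core import Feature, revcomp


# ---------------------------------------------------------------------------
# 3'-end families


@dataclass
class Family:
    family_id: str
    centroid_end30: str
    member_indices: list[int] = field(default_factory=list)


def end30(element_seq: str) -> str:
    """Last 30 bases of the element on its own strand (ends with CTAG)."""
    if len(element_seq) < 30:
        raise ValueError("element shorter than 30 bp has no terminal 30-mer")
    return element_seq[-30:]


def _end_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def pair_identity(a30: str, b30: str) -> float:
    """Identity of the two 30-mers: matching columns / alignment columns
    of the best global alignment (end gaps penalized)."""
    if len(a30) != 30 or len(b30) != 30:
        raise ValueError("pair_identity expects 30-bp sequences")
    aligner = _end_aligner()
    aln = aligner.align(a30, b30)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def greedy_cluster(
    ends: Sequence[str], id_threshold: float = 0.80
) -> list[Family]:
    """Greedy centroid clustering of 3'-end 30-mers.

    Unique sequences are processed in order of decreasing abundance
    (number of identical copies), ties by first occurrence; each joins
    the best existing centroid with identity >= `id_threshold`, else
    founds a new family.  Deterministic; >= 0.80 is inclusive.
    """
    first_seen: dict[str, int] = {}
    occurrences: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(ends):
        occurrences[s].append(i)
        first_seen.setdefault(s, i)
    order = sorted(occurrences, key=lambda s: (-len(occurrences[s]), first_seen[s]))
    aligner = _end_aligner()
    families: list[Family] = []
    for s in order:
        best_fam: Family | None = None
        best_id = -1.0
        for fam in families:
            aln = aligner.align(s, fam.centroid_end30)[0]
            c = aln.counts()
            ident = c.identities / (c.identities + c.mismatches + c.gaps)
            if ident >= id_threshold and ident > best_id:
                best_fam, best_id = fam, ident
        if best_fam is None:
            best_fam = Family(f"fam{len(families) + 1}", s)
            families.append(best_fam)
        best_fam.member_indices.extend(occurrences[s])
    for fam in families:
        fam.member_indices.sort()
    return families


def conserved_end_count(families: Sequence[Family], count_all: bool = False) -> int:
    """Number of conserved 3' ends: members of families of size >= 2 by
    default, or every clustered element with `count_all`."""
    if count_all:
        return sum(len(f.member_indices) for f in families)
    return sum(len(f.member_indices) for f in families if len(f.member_indices) >= 2)


# ---------------------------------------------------------------------------
# gene-fragment capture screen


@dataclass(frozen=True)
class CaptureMatch:
    element_index: int
    protein_id: str
    aln_len: int
    identity: float


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _six_frame_segments(seq: str, min_len: int) -> list[str]:
    """Stop-free translated segments of length >= min_len from all six
    frames (alignments can therefore never span a stop codon)."""
    segs: list[str] = []
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            aa = str(Seq(sub).translate())
            segs.extend(p for p in aa.split("*") if len(p) >= min_len)
    return segs


def capture_screen(
    elements: Sequence[str],
    proteins: dict[str, str],
    min_aln_len: int = 50,
    min_identity: float = 0.85,
) -> list[CaptureMatch]:
    """Screen elements for captured gene fragments.

    Each element is translated in six frames; stop-free segments are
    locally aligned (BLOSUM62, affine gaps) against every protein.  An
    alignment strictly longer than `min_aln_len` columns with identity
    >= `min_identity` is a match; one match per (element, protein) pair
    is reported.
    """
    if not proteins:
        raise ValueError("empty protein set")
    aligner = _protein_aligner()
    out: list[CaptureMatch] = []
    for i, elem in enumerate(elements):
        segs = _six_frame_segments(elem, min_aln_len + 1)
        for pid, prot in proteins.items():
            best: CaptureMatch | None = None
            for seg in segs:
                if aligner.score(seg, prot) < 2 * min_aln_len:  # cheap prefilter
                    continue
                aln = aligner.align(seg, prot)[0]
                c = aln.counts()
                cols = c.identities + c.mismatches + c.gaps
                ident = c.identities / cols if cols else 0.0
                if cols > min_aln_len and ident >= min_identity:
                    if best is None or cols > best.aln_len:
                        best = CaptureMatch(i, pid, cols, ident)
            if best is not None:
                out.append(best)
    return out


# ---------------------------------------------------------------------------
# window statistics and densities


@dataclass
class WindowStats:
    seq_id: str
    start: int
    end: int
    counts: Counter

    @property
    def gene_count(self) -> int:
        return self.counts.get("gene", 0)


def window_counts(
    features: Sequence[Feature],
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> list[WindowStats]:
    """Count features per non-overlapping window, each feature exactly
    once: it goes to the window covering the larger share of its length,
    ties to the lower-coordinate window."""
    wins: dict[str, list[WindowStats]] = {}
    for sid, n in chrom_lengths.items():
        wins[sid] = [
            WindowStats(sid, s, min(s + window, n), Counter())
            for s in range(0, n, window)
        ]
    for f in features:
        if f.seq_id not in chrom_lengths:
            raise ValueError(f"feature on unknown sequence {f.seq_id}")
        if f.end > chrom_lengths[f.seq_id]:
            raise ValueError(f"feature [{f.start},{f.end}) beyond end of {f.seq_id}")
        best_w = None
        best_ov = -1
        for wi in range(f.start // window, (f.end - 1) // window + 1):
            w = wins[f.seq_id][wi]
            ov = min(f.end, w.end) - max(f.start, w.start)
            if ov > best_ov:  # strict: ties keep the earlier window
                best_w, best_ov = w, ov
        best_w.counts[f.klass] += 1
    return [w for sid in chrom_lengths for w in wins[sid]]


def density_correlation(
    x_counts: Sequence[float],
    y_counts: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float] | None:
    """Correlation between two per-window count vectors.

    Pearson r with the two-sided p-value from t = r*sqrt((n-2)/(1-r^2))
    on n-2 df; Spearman by flag.  Returns None when either vector has
    zero variance (correlation undefined, not 0).
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    if method == "spearman":
        res = _stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * _stats.t.sf(abs(t), n - 2)
    return r, float(p)


def helitron_density(n_conserved_3prime_ends: int, genome_size_mb: float) -> float:
    """Elements per Mb: conserved 3'-end count over genome size in Mb."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return n_conserved_3prime_ends / genome_size_mb


def chromosome_enrichment(per_chromosome_density: dict[str, float]) -> list[str]:
    """Chromosomes whose density exceeds the across-chromosome mean by
    more than one population SD."""
    if len(per_chromosome_density) < 2:
        raise ValueError("need at least 2 chromosomes")
    vals = np.array(list(per_chromosome_density.values()), dtype=float)
    mean, sd = float(np.mean(vals)), float(np.std(vals))
    return [c for c, d in per_chromosome_density.items() if d > mean + sd]
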