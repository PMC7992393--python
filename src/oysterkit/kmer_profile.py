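"""k-mer spectrum construction and peak-based genome profiling.

A canonical k-mer spectrum (histogram of depth -> number of distinct
k-mers) from whole-genome reads of a diploid individual is bimodal: k-mers
spanning a heterozygous site occur on one haplotype only and pile up at
half the depth of homozygous k-mers.  From the two peaks the haploid
genome size and the per-base heterozygosity can be estimated in closed
form:

* size = (total k-mer mass above the error cutoff) / homozygous peak depth
* heterozygosity h solves  F = 1 - (1 - h)^k,  where F is the fraction of
  informative k-mer mass that sits in the heterozygous peak (a window of k
  bases is heterozygous if any of its bases differs between haplotypes).

This is a transparent simplification of mixture-model fitters such as
GenomeScope: no negative-binomial mixture is fitted; the error cutoff is
the first local minimum of the smoothed histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


class SpectrumError(ValueError):
    pass


@dataclass
class KmerSpectrum:
    """Histogram of canonical k-mer depths; hist[d] = distinct k-mers at depth d."""

    k: int
    hist: np.ndarray

    def __post_init__(self) -> None:
        self.hist = np.asarray(self.hist, dtype=np.int64)
        if np.any(self.hist < 0):
            raise SpectrumError("negative histogram counts")

    @property
    def total_instances(self) -> int:
        d = np.arange(len(self.hist), dtype=np.int64)
        return int(np.sum(d * self.hist))


@dataclass
class PeakFit:
    het_peak_depth: int | None
    hom_peak_depth: int
    error_cutoff_depth: int
    genome_size_bp: float
    heterozygosity_fraction: float | None


def _canonical_codes(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for every valid window of an encoded array
    (code 4 marks N or read boundaries; windows touching it are dropped)."""
    m = len(seq_codes) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        chunk = seq_codes[j : j + m]
        bad |= chunk == 4
        c = (chunk & 3).astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | c
        rev |= (np.uint64(3) - c) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[~bad]


def count_kmers(reads: Iterable[str], k: int, chunk_bases: int = 8_000_000) -> KmerSpectrum:
    """Count canonical k-mers (lexicographic min of k-mer and its reverse
    complement as 2-bit codes); k-mers containing N are skipped.

    The histogram conserves mass: sum(depth * count) equals the number of
    counted k-mer instances.
    """
    if k % 2 == 0:
        raise SpectrumError("k must be odd (even k makes canonicalization ambiguous)")
    if not (1 < k <= 31):
        raise SpectrumError("k must be in (1, 31]")
    parts: list[np.ndarray] = []
    buf: list[str] = []
    size = 0
    n_reads = 0

    def _flush() -> None:
        nonlocal buf, size
        if not buf:
            return
        text = "N".join(buf)
        codes = _ENC[np.frombuffer(text.encode(), dtype=np.uint8)]
        parts.append(_canonical_codes(codes, k))
        buf, size = [], 0

    for read in reads:
        n_reads += 1
        buf.append(read)
        size += len(read)
        if size >= chunk_bases:
            _flush()
    _flush()
    if n_reads == 0:
        raise SpectrumError("no reads supplied")
    if not parts:
        return KmerSpectrum(k, np.zeros(1, dtype=np.int64))
    allk = np.concatenate(parts)
    if len(allk) == 0:
        return KmerSpectrum(k, np.zeros(1, dtype=np.int64))
    allk.sort(kind="stable")
    boundaries = np.flatnonzero(np.diff(allk)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(allk)]))
    depths = ends - starts
    hist = np.bincount(depths)
    return KmerSpectrum(k, hist)


def _smooth(hist: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average; depth-0 bin ignored (set to 0)."""
    h = hist.astype(float).copy()
    if len(h) > 0:
        h[0] = 0.0
    kernel = np.ones(width) / width
    return np.convolve(h, kernel, mode="same")


def error_cutoff(spectrum: KmerSpectrum, width: int = 3) -> int:
    """Depth at the first local minimum of the smoothed histogram."""
    sm = _smooth(spectrum.hist, width)
    for d in range(1, len(sm) - 1):
        if sm[d] <= sm[d - 1] and sm[d] < sm[d + 1]:
            return d
    return 1


def find_peaks(
    spectrum: KmerSpectrum,
    width: int = 3,
    diploid_ratio: tuple[float, float] = (1.6, 2.4),
    min_partner_frac: float = 0.10,
) -> tuple[int | None, int]:
    """Locate the heterozygous and homozygous peaks of the spectrum.

    Local maxima of the smoothed histogram above the error trough are
    candidate peaks.  If a second maximum sits at roughly half (or twice)
    the depth of the strongest one — depth ratio within `diploid_ratio` —
    and is at least `min_partner_frac` of its height (so shot noise in the
    sparse tail is not mistaken for a peak), the pair is returned as
    (het, hom); otherwise (None, peak).
    """
    sm = _smooth(spectrum.hist, width)
    cut = error_cutoff(spectrum, width)
    maxima: list[int] = []
    for d in range(max(cut, 1), len(sm)):
        left = sm[d - 1] if d - 1 >= 0 else -np.inf
        right = sm[d + 1] if d + 1 < len(sm) else -np.inf
        if sm[d] > left and sm[d] >= right:
            maxima.append(d)
    if not maxima:
        raise SpectrumError("spectrum unresolvable: no peak above error cutoff")
    primary = max(maxima, key=lambda d: sm[d])
    lo, hi = diploid_ratio
    partners = []
    for d in maxima:
        if d == primary:
            continue
        ratio = max(primary, d) / min(primary, d)
        if lo <= ratio <= hi and sm[d] >= min_partner_frac * sm[primary]:
            partners.append(d)
    if not partners:
        return None, primary
    partner = max(partners, key=lambda d: sm[d])
    het, hom = min(primary, partner), max(primary, partner)
    return het, hom


def refine_peak(spectrum: KmerSpectrum, peak: int, width: int = 3) -> float:
    """Sub-integer peak depth by quadratic interpolation of the smoothed
    histogram around the integer peak."""
    sm = _smooth(spectrum.hist, width)
    if not (1 <= peak < len(sm) - 1):
        return float(peak)
    y0, y1, y2 = sm[peak - 1], sm[peak], sm[peak + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(peak)
    return float(peak + 0.5 * (y0 - y2) / denom)


def estimate_genome_size(
    spectrum: KmerSpectrum, hom_peak_depth: float, cutoff: int | None = None
) -> float:
    """Haploid-equivalent genome size: total informative k-mer mass divided
    by the homozygous peak depth."""
    if cutoff is None:
        cutoff = error_cutoff(spectrum)
    d = np.arange(len(spectrum.hist), dtype=np.int64)
    mass = float(np.sum(d[cutoff:] * spectrum.hist[cutoff:]))
    if mass == 0:
        raise SpectrumError("no k-mer mass above the error cutoff")
    if hom_peak_depth <= 0:
        raise SpectrumError("non-positive homozygous peak depth")
    return mass / hom_peak_depth


def estimate_heterozygosity(
    spectrum: KmerSpectrum,
    peaks: tuple[int | None, int],
    k: int | None = None,
    cutoff: int | None = None,
    width: int = 3,
) -> float | None:
    """Per-base heterozygosity from the het-peak mass fraction.

    F = (k-mer mass between the error cutoff and the het/hom valley) /
    (total informative mass); a k-base window is heterozygous if any base
    differs between haplotypes, so h = 1 - (1 - F)^(1/k).  Returns None
    when the het peak is absent.
    """
    het, hom = peaks
    if het is None:
        return None
    if k is None:
        k = spectrum.k
    if cutoff is None:
        cutoff = error_cutoff(spectrum, width)
    sm = _smooth(spectrum.hist, width)
    valley = het + int(np.argmin(sm[het : hom + 1]))
    d = np.arange(len(spectrum.hist), dtype=np.int64)
    total = float(np.sum(d[cutoff:] * spectrum.hist[cutoff:]))
    het_mass = float(np.sum(d[cutoff:valley] * spectrum.hist[cutoff:valley]))
    if total == 0:
        raise SpectrumError("no informative k-mer mass")
    F = het_mass / total
    return 1.0 - (1.0 - F) ** (1.0 / k)


def fit_spectrum(spectrum: KmerSpectrum) -> PeakFit:
    """Full profile: peaks, error cutoff, genome size, heterozygosity."""
    het, hom = find_peaks(spectrum)
    cut = error_cutoff(spectrum)
    size = estimate_genome_size(spectrum, refine_peak(spectrum, hom), cut)
    h = estimate_heterozygosity(spectrum, (het, hom), cutoff=cut)
    return PeakFit(het, hom, cut, size, h)


def write_histogram_tsv(spectrum: KmerSpectrum, path) -> None:
    """Jellyfish-histo-compatible TSV: depth <TAB> count."""
    with open(path, "w") as fh:
        for d in range(1, len(spectrum.hist)):
            if spectrum.hist[d]:
                fh.write(f"{d}\t{int(spectrum.hist[d])}\n")
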