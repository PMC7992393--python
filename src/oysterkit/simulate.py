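"""Synthetic assemblies, elements, coverage, reads and markers with truth.

The generator emulates the features of a highly heterozygous bivalve
genome that the downstream stages consume: Helitron-like elements with
canonical termini and hairpin (length ~ Normal(1092, 558) truncated at
200 bp; AT target-site insertion with probability 0.86), haplotig
duplicates at a few percent divergence, GC-biased short-read coverage,
diploid read sets, and linkage-map markers.

Planted elements are emitted mutation-free by default so that detector
correctness can be separated from robustness.  To make the
generator/detector round trip exact, element-internal sequence is
constrained never to contain the ``TC`` dinucleotide except at the 5'
terminus (otherwise an interior TC closer to the 3' end would win the
nearest-upstream pairing and shift the recovered 5' coordinate).
Palindromic parts additionally avoid ``GA`` so their reverse complements
stay TC-free.

A single seeded :class:`numpy.random.Generator` drives every stage;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .heliscan import Hairpin
from .io_core import DepthTrack, Feature, MarkerRecord, SeqRecord, SVRecord, revcomp

_BASES = "ACGT"


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.33) -> str:
    """Random sequence with the given expected GC fraction."""
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[i] for i in idx)


def _constrained_seq(
    rng: np.random.Generator,
    n: int,
    gc: float = 0.33,
    forbid_ga: bool = False,
    prev_char: str | None = None,
    next_char: str | None = None,
) -> str:
    """Sequence avoiding the TC dinucleotide (and optionally GA), including
    across the junctions to `prev_char` before and `next_char` after.

    Drawn iid then repaired by resampling violating positions (vectorized).
    """
    if n == 0:
        return ""
    probs = _base_probs(gc)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    idx = rng.choice(4, size=n, p=probs)
    prev0 = code.get(prev_char, -1)
    for _ in range(500):
        prev_arr = np.empty(n, dtype=np.int64)
        prev_arr[0] = prev0
        prev_arr[1:] = idx[:-1]
        bad = (prev_arr == 3) & (idx == 1)
        if forbid_ga:
            bad |= (prev_arr == 2) & (idx == 0)
        if next_char == "C":
            bad |= (np.arange(n) == n - 1) & (idx == 3)
        if forbid_ga and next_char == "A":
            bad |= (np.arange(n) == n - 1) & (idx == 2)
        nbad = int(bad.sum())
        if nbad == 0:
            break
        idx[bad] = rng.choice(4, size=nbad, p=probs)
    else:
        raise RuntimeError("failed to draw a constrained sequence")
    return np.array([65, 67, 71, 84], dtype=np.uint8)[idx].tobytes().decode()


def _gc_rich_stem(rng: np.random.Generator, n: int, min_gc: float = 0.6) -> str:
    """TC/GA-free stem with GC fraction >= min_gc (rejection sampled)."""
    for _ in range(1000):
        s = _constrained_seq(rng, n, gc=0.72, forbid_ga=True)
        if (s.count("G") + s.count("C")) / n >= min_gc:
            return s
    raise RuntimeError("failed to draw a GC-rich stem")


# ---------------------------------------------------------------------------
# element generator


@dataclass
class ElementSpec:
    """Parameters of the planted Helitron-like elements."""

    length_mean: float = 1092.0
    length_sd: float = 558.0
    length_floor: int = 200
    hairpin_span: tuple[int, int] = (16, 20)
    hairpin_gap_to_3prime: tuple[int, int] = (2, 12)
    p_at_site: float = 0.86
    with_subtir: float = 0.342  # 257 of 751 elements carry a subTIR
    with_5prime_ir: float = 0.33  # of subTIR-bearing elements
    with_microsat: float = 0.0013  # 1 of 751
    subtir_len: tuple[int, int] = (12, 16)
    family_seed_3prime: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_at_site <= 1.0):
            raise ValueError("p_at_site must be a probability")
        for lo, hi in (self.hairpin_span, self.hairpin_gap_to_3prime, self.subtir_len):
            if lo > hi:
                raise ValueError(f"inconsistent range ({lo}, {hi})")
        if not (16 <= self.hairpin_span[0] and self.hairpin_span[1] <= 20):
            raise ValueError("hairpin span must lie within [16, 20]")
        if self.family_seed_3prime is not None:
            _parse_family_seed(self.family_seed_3prime)

    def length_mean_truncated(self) -> float:
        """Analytic mean of the truncated length distribution."""
        a = (self.length_floor - self.length_mean) / self.length_sd
        return float(
            stats.truncnorm.mean(a, np.inf, loc=self.length_mean, scale=self.length_sd)
        )


@dataclass
class ElementTruth:
    """Ground truth for one generated element (coordinates element-relative)."""

    length: int
    hairpin: Hairpin
    subtir: tuple[int, int, int] | None  # (pos5, pos3, length)
    ir5: tuple[int, int] | None  # (pos, length)
    microsat: tuple[int, str, int] | None  # (pos, unit, copies)
    family: str | None

    @property
    def has_subtir(self) -> bool:
        return self.subtir is not None

    @property
    def has_ir5(self) -> bool:
        return self.ir5 is not None

    @property
    def has_microsat(self) -> bool:
        return self.microsat is not None


def make_family_seed(rng: np.random.Generator) -> str:
    """A 30-bp terminal family seed: 20-bp perfect palindrome + 6-bp gap + CTAG."""
    stem = _gc_rich_stem(rng, 10)
    gap = "".join(
        "ATG"[rng.choice(3, p=np.array([0.45, 0.35, 0.2]))] for _ in range(6)
    )
    if gap[-1] == "T":  # avoid TC across the gap/CTAG junction
        gap = gap[:-1] + "A"
    return stem + revcomp(stem) + gap + "CTAG"


def _parse_family_seed(seed: str) -> tuple[str, str]:
    if len(seed) != 30 or not seed.endswith("CTAG"):
        raise ValueError("family seed must be 30 bp ending in CTAG")
    stem, gap = seed[:10], seed[20:26]
    if seed[:20] != stem + revcomp(stem):
        raise ValueError("family seed must start with a 20-bp perfect palindrome")
    if "C" in gap or gap[-1] == "T":
        raise ValueError("family seed gap region may not contain C or end in T")
    return stem, gap


def make_element(
    spec: ElementSpec, rng: np.random.Generator, family: str | None = None
) -> tuple[str, ElementTruth]:
    """Emit one element sequence plus its ground truth.

    The sequence starts ``TC``, ends ``CTAG``, and carries a perfect
    GC-rich palindromic hairpin (span 16-20, loop 0) ending within the
    configured gap upstream of the terminal CTAG.  Requested substructures
    (subTIR, 5' IR, 5' microsatellite) are planted inside 50-bp terminal
    windows.
    """
    # length
    a = (spec.length_floor - spec.length_mean) / spec.length_sd
    length = int(
        round(
            stats.truncnorm.rvs(
                a, np.inf, loc=spec.length_mean, scale=spec.length_sd, random_state=rng
            )
        )
    )
    length = max(length, spec.length_floor)

    want_subtir = rng.random() < spec.with_subtir
    want_ir = want_subtir and rng.random() < spec.with_5prime_ir
    want_ms = rng.random() < spec.with_microsat

    # 3' hairpin + gap (from the family seed when given)
    if spec.family_seed_3prime is not None:
        stem, gap_seq = _parse_family_seed(spec.family_seed_3prime)
        span = 20
    else:
        lo, hi = spec.hairpin_span
        evens = [s for s in range(lo, hi + 1) if s % 2 == 0]
        span = int(rng.choice(evens))
        stem = _gc_rich_stem(rng, span // 2)
        gmin, gmax = spec.hairpin_gap_to_3prime
        if want_subtir:
            # subTIR 3' copy must fit inside the last 50 bp too
            gmax = min(gmax, 50 - 4 - span - 1 - spec.subtir_len[1])
            gmax = max(gmax, gmin)
        glen = int(rng.integers(gmin, gmax + 1))
        gap_seq = _constrained_seq(rng, glen, gc=0.0, prev_char=stem[0], next_char=None)
        gap_seq = gap_seq.replace("C", "A")  # no C: no internal CTAG or TC
        if gap_seq and gap_seq[-1] == "T":
            gap_seq = gap_seq[:-1] + "A"
    hairpin_seq = stem + revcomp(stem)

    # subTIR
    if want_subtir:
        max_s5 = spec.subtir_len[1]
        if want_ir:
            # budget: TC + ms + s5 + ir5 + three 1-bp fillers <= 50
            ms_budget = 12 if want_ms else 0
            max_s5 = min(max_s5, (50 - 5 - 2 - ms_budget) // 2)
        s5_len = int(rng.integers(spec.subtir_len[0], max(max_s5, spec.subtir_len[0]) + 1))
        s5 = _constrained_seq(rng, s5_len, gc=0.4, forbid_ga=True)
        s3 = revcomp(s5)
    else:
        s5 = s3 = ""

    # microsatellite
    if want_ms:
        unit = ["CA", "AG", "CAA", "AAG"][int(rng.integers(4))]
        copies = int(rng.integers(5, 7)) if len(unit) == 2 else int(rng.integers(3, 5))
        ms = unit * copies
    else:
        unit, copies, ms = "", 0, ""

    ir = revcomp(s5) if want_ir else ""

    # assemble: TC f1 [ms] f2 [ir] f3 [s5] interior [s3] f5 hairpin gap CTAG
    tail_fixed = len(s3) + (1 if s3 else 0) + len(hairpin_seq) + len(gap_seq) + 4
    head_parts = [p for p in (ms, ir, s5) if p]
    head_fixed = 2 + sum(len(p) for p in head_parts) + len(head_parts)  # 1-bp fillers
    interior_len = length - head_fixed - tail_fixed
    if interior_len < 1:
        interior_len = 1
        length = head_fixed + tail_fixed + 1

    def filler(n: int, prev: str, nxt: str | None) -> str:
        return _constrained_seq(rng, n, gc=0.33, prev_char=prev, next_char=nxt)

    pieces: list[str] = ["TC"]
    pos = 2
    truth_ms = truth_ir = None
    truth_s5_pos = None
    for part in head_parts:
        f = filler(1, pieces[-1][-1], part[0])
        pieces.append(f)
        pos += 1
        if part is ms and want_ms:
            truth_ms = (pos, unit, copies)
        elif part is ir and want_ir:
            truth_ir = (pos, len(ir))
        elif part is s5 and want_subtir:
            truth_s5_pos = pos
        pieces.append(part)
        pos += len(part)

    nxt = s3[0] if s3 else hairpin_seq[0]
    pieces.append(filler(interior_len, pieces[-1][-1], nxt))
    pos += interior_len
    truth_subtir = None
    if s3:
        truth_subtir = (truth_s5_pos, pos, len(s5))
        pieces.append(s3)
        pos += len(s3)
        pieces.append(filler(1, s3[-1], hairpin_seq[0]))
        pos += 1
    hp_start = pos
    pieces.extend([hairpin_seq, gap_seq, "CTAG"])
    seq = "".join(pieces)

    if truth_subtir is not None:
        # keep the planted inverted-repeat pair from extending by chance:
        # the bases flanking the two copies must not complement each other,
        # or detectors would recover a longer subTIR than was planted
        chars = list(seq)
        p5, p3, sl = truth_subtir
        _COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i, j in ((p3 + sl, p5 - 1), (p3 - 1, p5 + sl)):
            if chars[i] == _COMP[chars[j]]:
                banned = {
                    _COMP[chars[j]],
                    "C" if chars[i - 1] == "T" else "",
                    "T" if chars[i + 1] == "C" else "",
                }
                options = [b for b in _BASES if b not in banned]
                chars[i] = options[int(rng.integers(len(options)))]
        seq = "".join(chars)

    hairpin = Hairpin(
        hp_start, hp_start + span, span // 2, 0, 0,
        (stem.count("G") + stem.count("C")) / len(stem),
    )
    assert len(seq) == length, (len(seq), length)
    assert seq.find("TC", 1) == -1, "internal TC would break terminus pairing"
    truth = ElementTruth(
        length=length, hairpin=hairpin, subtir=truth_subtir,
        ir5=truth_ir, microsat=truth_ms, family=family,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# planting


@dataclass
class PlantedElement:
    """Truth record for one planted element, in modified-host coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    at_site: bool
    truth: ElementTruth


def plant_many(
    host: SeqRecord,
    groups: Sequence[tuple[int, ElementSpec, str | None]],
    rng: np.random.Generator,
    p_reverse: float = 0.5,
) -> tuple[SeqRecord, list[PlantedElement]]:
    """Insert a mixture of element groups in a single pass.

    `groups` is a sequence of (count, spec, family label).  All insertion
    points are chosen up front on the unmodified host, so truth
    coordinates stay valid and planted intervals never overlap — planting
    in several separate passes would shift or split earlier elements.
    Each element inserts at an AT target site (between the A and the T)
    with its spec's probability, else at a uniform non-AT position.
    """
    jobs: list[tuple[ElementSpec, str | None]] = []
    for count, spec, family in groups:
        jobs += [(spec, family)] * count
    n = len(jobs)
    if n == 0:
        return host, []
    seq = host.seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    at_idx = np.flatnonzero((arr[:-1] == ord("A")) & (arr[1:] == ord("T"))) + 1
    non_at = np.setdiff1d(np.arange(1, len(seq)), at_idx, assume_unique=False)

    want_at = np.array([rng.random() < spec.p_at_site for spec, _ in jobs])
    n_at, n_non = int(want_at.sum()), int((~want_at).sum())
    if n_at > len(at_idx) or n_non > len(non_at):
        raise ValueError(
            f"cannot place {n} elements without overlap in host of length {len(seq)}"
        )
    chosen_at = rng.choice(at_idx, size=n_at, replace=False) if n_at else np.empty(0, int)
    chosen_non = (
        rng.choice(non_at, size=n_non, replace=False) if n_non else np.empty(0, int)
    )
    points: list[tuple[int, bool, int]] = []  # (host position, at flag, job index)
    job_at = iter(np.flatnonzero(want_at))
    job_non = iter(np.flatnonzero(~want_at))
    for i in chosen_at:
        points.append((int(i), True, int(next(job_at))))
    for i in chosen_non:
        points.append((int(i), False, int(next(job_non))))
    points.sort()

    parts: list[str] = []
    planted: list[PlantedElement] = []
    prev = 0
    offset = 0
    for i, is_at, j in points:
        spec, family = jobs[j]
        elem_seq, truth = make_element(spec, rng, family=family)
        strand = "-" if rng.random() < p_reverse else "+"
        ins = elem_seq if strand == "+" else revcomp(elem_seq)
        parts.append(seq[prev:i])
        start = i + offset
        parts.append(ins)
        planted.append(
            PlantedElement(host.id, start, start + len(ins), strand, is_at, truth)
        )
        offset += len(ins)
        prev = i
    parts.append(seq[prev:])
    return SeqRecord(host.id, "".join(parts)), planted


def plant_elements(
    host: SeqRecord,
    n: int,
    spec: ElementSpec,
    rng: np.random.Generator,
    p_reverse: float = 0.5,
) -> tuple[SeqRecord, list[PlantedElement]]:
    """Insert `n` elements of one spec; see :func:`plant_many`."""
    return plant_many(host, [(n, spec, None)], rng, p_reverse=p_reverse)


# ---------------------------------------------------------------------------
# whole-assembly simulation


@dataclass
class AssemblyConfig:
    """Synthetic-assembly layout: chromosomes, contigs, haplotigs, features."""

    n_chromosomes: int = 3
    chrom_len: int = 400_000
    gc: float = 0.33
    contigs_per_chrom: int = 4
    haplotig_fraction: float = 0.4
    haplotig_divergence: float = 0.03
    haplotig_cover: tuple[float, float] = (0.5, 1.0)
    gene_per_100kb: float = 5.0
    repeat_per_100kb: dict = field(
        default_factory=lambda: {
            "DNA_transposon": 15.0,
            "LTR": 4.0,
            "LINE": 3.0,
            "satellite": 2.0,
            "simple_repeat": 6.0,
        }
    )
    n_elements_per_chrom: int = 0
    element_spec: ElementSpec = field(default_factory=ElementSpec)


@dataclass
class HaplotigTruth:
    contig_id: str
    source_id: str
    src_start: int
    src_end: int
    divergence: float


@dataclass
class AssemblyTruth:
    chrom_lengths: dict[str, int]
    contig_layout: dict[str, tuple[str, int, int]]  # contig -> (chrom, start, end)
    haplotigs: list[HaplotigTruth]
    features: list[Feature]  # chromosome coordinates
    elements: list[PlantedElement]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at the given per-base rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    lut = {ord(b): [ord(c) for c in _BASES if c != b] for b in _BASES}
    for i in hits:
        alts = lut.get(int(arr[i]))
        if alts:
            arr[i] = alts[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_assembly(
    config: AssemblyConfig, rng: np.random.Generator
) -> tuple[list[SeqRecord], AssemblyTruth]:
    """Generate chromosomes, split them into contigs, add divergent
    haplotig duplicates, and emit gene/repeat feature truth.

    Gene and repeat densities share a latent per-100kb intensity with
    opposite sign, producing the negative gene/repeat density correlation
    seen in repeat-rich genomes.
    """
    # annotations may overlap, but on average they must fit the window
    expected_bases = config.gene_per_100kb * 2250 + sum(
        config.repeat_per_100kb.values()
    ) * 1325
    if expected_bases > 100_000:
        raise ValueError("feature densities exceed window capacity")

    chroms: list[SeqRecord] = []
    features: list[Feature] = []
    elements: list[PlantedElement] = []
    chrom_lengths: dict[str, int] = {}
    for c in range(config.n_chromosomes):
        cid = f"chr{c + 1}"
        rec = SeqRecord(cid, random_seq(rng, config.chrom_len, config.gc))
        if config.n_elements_per_chrom > 0:
            rec, planted = plant_elements(
                rec, config.n_elements_per_chrom, config.element_spec, rng
            )
            elements.extend(planted)
        chroms.append(rec)
        chrom_lengths[cid] = len(rec.seq)

        n_blocks = len(rec.seq) // 100_000
        for b in range(n_blocks):
            u = rng.uniform(0.1, 0.9)
            base = b * 100_000
            n_genes = rng.poisson(2 * config.gene_per_100kb * u)
            for _ in range(n_genes):
                glen = int(rng.integers(500, 4000))
                s = int(rng.integers(base, base + 100_000 - glen))
                features.append(Feature(cid, s, s + glen, "+", "gene"))
            for klass, dens in config.repeat_per_100kb.items():
                n_rep = rng.poisson(2 * dens * (1 - u))
                for _ in range(n_rep):
                    rlen = int(rng.integers(150, 2500))
                    s = int(rng.integers(base, base + 100_000 - rlen))
                    features.append(Feature(cid, s, s + rlen, "+", klass))

    # contigs
    contigs: list[SeqRecord] = []
    layout: dict[str, tuple[str, int, int]] = {}
    for rec in chroms:
        k = config.contigs_per_chrom
        # even-sized splits with +-20% jitter so no contig is degenerate
        base = np.linspace(0, len(rec.seq), k + 1)
        jitter = rng.uniform(-0.2, 0.2, size=max(k - 1, 0)) * (len(rec.seq) / k)
        bounds = [0, *np.sort(base[1:-1] + jitter).astype(int).tolist(), len(rec.seq)]
        for j in range(k):
            cname = f"{rec.id}_ctg{j + 1}"
            s, e = bounds[j], bounds[j + 1]
            contigs.append(SeqRecord(cname, rec.seq[s:e]))
            layout[cname] = (rec.id, s, e)

    # haplotigs
    haplotigs: list[HaplotigTruth] = []
    n_hap = int(round(config.haplotig_fraction * len(contigs)))
    victims = rng.choice(len(contigs), size=min(n_hap, len(contigs)), replace=False)
    for k, vi in enumerate(sorted(int(v) for v in victims)):
        src = contigs[vi]
        cover = rng.uniform(*config.haplotig_cover)
        # haplotigs stay comfortably above the 10-kb removal floor
        hlen = max(15_000, int(cover * len(src.seq)))
        hlen = min(hlen, len(src.seq))
        s = int(rng.integers(0, len(src.seq) - hlen + 1))
        hseq = _mutate(src.seq[s : s + hlen], config.haplotig_divergence, rng)
        hid = f"htg{k + 1}_{src.id}"
        contigs.append(SeqRecord(hid, hseq))
        haplotigs.append(
            HaplotigTruth(hid, src.id, s, s + hlen, config.haplotig_divergence)
        )

    truth = AssemblyTruth(chrom_lengths, layout, haplotigs, features, elements)
    return contigs, truth


# ---------------------------------------------------------------------------
# depth, reads, markers, SVs


def simulate_depth(
    records: Sequence[SeqRecord],
    rng: np.random.Generator,
    mean_depth: float = 30.0,
    gc_bias_slope: float = 0.0,
    junk_ids: Sequence[str] = (),
    junk_factor: float = 0.1,
    window: int = 1000,
) -> list[DepthTrack]:
    """Per-base Poisson depth with a linear GC bias on 1-kb window means.

    Scaffolds listed in `junk_ids` receive `junk_factor` times the mean
    (several SD away from the global coverage), emulating low-accuracy
    sequence.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    junk = set(junk_ids)
    tracks: list[DepthTrack] = []
    for rec in records:
        n = len(rec.seq)
        lam = np.empty(n)
        for s in range(0, n, window):
            e = min(s + window, n)
            from .io_core import gc_fraction

            gc = gc_fraction(rec.seq[s:e])
            gc = 0.5 if gc is None else gc
            lam[s:e] = mean_depth * max(0.05, 1.0 + gc_bias_slope * (gc - 0.5))
        if rec.id in junk:
            lam *= junk_factor
        tracks.append(DepthTrack(rec.id, rng.poisson(lam).astype(float)))
    return tracks


def diploid_haplotypes(
    genome: str, heterozygosity: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Second haplotype derived by substituting at the heterozygosity rate."""
    return genome, _mutate(genome, heterozygosity, rng)


def simulate_reads(
    haplotypes: Sequence[str],
    rng: np.random.Generator,
    read_len: int = 150,
    depth: float = 30.0,
    err_rate: float = 0.0,
) -> list[str]:
    """Uniform reads from the given haplotypes at combined depth `depth`.

    Reads are drawn from both strands; substitution errors are applied at
    `err_rate` per base.  Homozygous k-mers then appear at an expected
    depth of ``depth * (read_len - k + 1) / read_len``.
    """
    glen = len(haplotypes[0])
    if read_len > glen:
        raise ValueError("read length exceeds genome length")
    n_reads = int(round(depth * glen / read_len))
    reads: list[str] = []
    hap_idx = rng.integers(0, len(haplotypes), size=n_reads)
    starts = rng.integers(0, glen - read_len + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    n_err = rng.binomial(read_len, err_rate, size=n_reads) if err_rate > 0 else None
    for r in range(n_reads):
        h = haplotypes[hap_idx[r]]
        s = int(starts[r])
        read = h[s : s + read_len]
        if n_err is not None and n_err[r] > 0:
            arr = list(read)
            for p in rng.integers(0, read_len, size=int(n_err[r])):
                old = arr[p]
                alts = [b for b in _BASES if b != old]
                arr[p] = alts[int(rng.integers(3))]
            read = "".join(arr)
        reads.append(revcomp(read) if flip[r] else read)
    return reads


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    lg: str
    order_index: int
    orientation: int  # +1 forward, -1 reversed
    length: int


def simulate_markers(
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    scaffolds_per_chrom: int = 3,
    markers_per_scaffold: int = 20,
    cm_noise_sd: float = 0.0,
    map_length_cm: float = 50.0,
    mapq_low_frac: float = 0.1,
) -> tuple[list[MarkerRecord], list[ScaffoldTruth]]:
    """Markers on scaffolds cut from each chromosome.

    Linkage group equals the true chromosome; cM grows linearly with
    physical position (total `map_length_cm` per chromosome) plus Gaussian
    noise; a `mapq_low_frac` fraction of markers receives MAPQ <= 16.
    """
    if markers_per_scaffold < 2:
        raise ValueError("need at least 2 markers per scaffold")
    markers: list[MarkerRecord] = []
    scaffolds: list[ScaffoldTruth] = []
    mid = 0
    for chrom, clen in chrom_lengths.items():
        k = scaffolds_per_chrom
        cuts = (
            np.sort(rng.choice(np.arange(clen // 10, clen), size=k - 1, replace=False))
            if k > 1
            else np.array([], dtype=int)
        )
        bounds = [0, *cuts.tolist(), clen]
        for j in range(k):
            s, e = bounds[j], bounds[j + 1]
            sid = f"{chrom}_scaf{j + 1}"
            orient = 1 if rng.random() < 0.5 else -1
            scaffolds.append(ScaffoldTruth(sid, chrom, j, orient, e - s))
            pos = np.sort(rng.choice(np.arange(e - s), size=markers_per_scaffold, replace=False))
            for p in pos:
                chrom_pos = s + int(p)
                cm = chrom_pos / clen * map_length_cm
                if cm_noise_sd > 0:
                    cm += rng.normal(0, cm_noise_sd)
                cm = max(cm, 0.0)
                aln_pos = int(p) if orient == 1 else (e - s) - 1 - int(p)
                low = rng.random() < mapq_low_frac
                mapq = int(rng.integers(0, 17)) if low else int(rng.integers(30, 61))
                mid += 1
                markers.append(
                    MarkerRecord(f"m{mid}", chrom, float(cm), sid, aln_pos, mapq)
                )
    return markers, scaffolds


def simulate_svs(
    lengths: dict[str, int],
    rng: np.random.Generator,
    n_errors: int = 20,
    n_benign: int = 80,
) -> tuple[list[SVRecord], list[bool]]:
    """SV call set with planted assembly errors.

    Errors: length >= 50 and reference-support ratio < 0.2.  Benign calls
    are either small or well supported by the reference allele.
    """
    ids = list(lengths)
    recs: list[SVRecord] = []
    labels: list[bool] = []
    for _ in range(n_errors):
        sid = ids[int(rng.integers(len(ids)))]
        alt = int(rng.integers(15, 40))
        ref = int(rng.integers(0, max(1, int(0.18 * alt))))
        recs.append(
            SVRecord(sid, int(rng.integers(1, lengths[sid])), int(rng.integers(50, 5000)), ref, alt)
        )
        labels.append(True)
    for _ in range(n_benign):
        sid = ids[int(rng.integers(len(ids)))]
        if rng.random() < 0.5:
            svlen = int(rng.integers(1, 50))  # too small
            ref, alt = int(rng.integers(0, 5)), int(rng.integers(10, 30))
        else:
            svlen = int(rng.integers(50, 5000))
            alt = int(rng.integers(5, 20))
            ref = int(rng.integers(int(0.4 * alt) + 1, 3 * alt + 2))
        recs.append(SVRecord(sid, int(rng.integers(1, lengths[sid])), svlen, ref, alt))
        labels.append(False)
    return recs, labels
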