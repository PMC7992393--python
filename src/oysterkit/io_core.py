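"""Readers/writers for on-disk formats plus basic sequence utilities.

All coordinates inside the package are 0-based half-open on the forward
strand.  Adapters for 1-based formats (VCF, GFF3) shift by one on read and
write so the conversions are exact inverses.  IUPAC ambiguity codes other
than ``N`` are rejected rather than silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN")

FEATURE_CLASSES = (
    "gene",
    "DNA_transposon",
    "LTR",
    "LINE",
    "satellite",
    "simple_repeat",
    "helitron",
    "other",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised on malformed or out-of-contract input."""


# ---------------------------------------------------------------------------
# sequence records


@dataclass
class SeqRecord:
    """A named DNA sequence over {A, C, G, T, N}, uppercase-normalized."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Lowercase bases are normalized to uppercase.  Duplicate ids and empty
    records are hard errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N; involution on valid input."""
    bad = set(seq.upper()) - ALPHABET
    if bad:
        raise FormatError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float | None:
    """(G+C)/(A+C+G+T); N excluded from the denominator.

    Returns None when the sequence is all N.  Empty input is a hard error.
    """
    if len(seq) == 0:
        raise FormatError("gc_fraction of empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        return None
    return gc / acgt


# ---------------------------------------------------------------------------
# features (BED / GFF3)


@dataclass
class Feature:
    """A located genomic feature with a repeat/gene class label."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    klass: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.klass not in FEATURE_CLASSES:
            raise FormatError(f"unknown feature class {self.klass!r}")

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path) -> list[Feature]:
    """Read features from BED (0-based half-open; name column = class)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"malformed BED line: {line!r}")
            klass = parts[3] if len(parts) > 3 else "other"
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(
                Feature(parts[0], int(parts[1]), int(parts[2]), strand, klass)
            )
    return feats


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.seq_id}\t{f.start}\t{f.end}\t{f.klass}\t0\t{f.strand}\n"
            )


def read_gff3_genes(path: str | Path) -> list[Feature]:
    """Read gene features from GFF3 (read-only subset; 1-based closed -> 0-based)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            if parts[2] != "gene":
                continue
            strand = parts[6] if parts[6] in ("+", "-") else "."
            feats.append(
                Feature(parts[0], int(parts[3]) - 1, int(parts[4]), strand, "gene")
            )
    return feats


def validate_features(features: Sequence[Feature], lengths: dict[str, int]) -> None:
    """Check every feature lies within its sequence when resolvable."""
    for f in features:
        if f.seq_id in lengths and f.end > lengths[f.seq_id]:
            raise FormatError(
                f"feature [{f.start}, {f.end}) exceeds length "
                f"{lengths[f.seq_id]} of {f.seq_id}"
            )


# ---------------------------------------------------------------------------
# depth tracks (bedGraph)


@dataclass
class DepthTrack:
    """Per-base read depth for one sequence."""

    seq_id: str
    depths: np.ndarray  # per-base, non-negative

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise FormatError("depth track must be one-dimensional")
        if np.any(self.depths < 0):
            raise FormatError(f"negative depths in track {self.seq_id}")


def read_bedgraph(path: str | Path, lengths: dict[str, int]) -> dict[str, DepthTrack]:
    """Expand a bedGraph of (chrom, start, end, value) runs to per-base tracks.

    Runs must be sorted and non-overlapping per chromosome; positions not
    covered by any run default to depth 0.
    """
    arrays = {sid: np.zeros(n, dtype=float) for sid, n in lengths.items()}
    last_end: dict[str, int] = {sid: 0 for sid in lengths}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            sid, start, end, value = line.split("\t")
            start, end = int(start), int(end)
            if sid not in arrays:
                raise FormatError(f"bedGraph chrom {sid!r} not in assembly")
            if start < last_end[sid]:
                raise FormatError(f"unsorted/overlapping bedGraph runs on {sid}")
            if end > lengths[sid]:
                raise FormatError(f"bedGraph run beyond end of {sid}")
            arrays[sid][start:end] = float(value)
            last_end[sid] = end
    return {sid: DepthTrack(sid, arr) for sid, arr in arrays.items()}


def write_bedgraph(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """Write per-base tracks as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for tr in tracks:
            d = np.asarray(tr.depths)
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                v = d[s]
                sv = f"{int(v)}" if float(v).is_integer() else f"{v:g}"
                fh.write(f"{tr.seq_id}\t{s}\t{e}\t{sv}\n")


# ---------------------------------------------------------------------------
# structural variants (VCF, read-only subset)


@dataclass
class SVRecord:
    """One structural variant with reference/alternate read support."""

    seq_id: str
    pos: int  # 1-based, as in VCF
    sv_len: int
    ref_support: int
    alt_support: int

    def __post_init__(self) -> None:
        if self.sv_len < 0:
            raise FormatError("negative SV length")
        if self.ref_support < 0 or self.alt_support < 0:
            raise FormatError("negative SV support counts")


def read_sv_vcf(
    path: str | Path,
    ref_key: str = "DR",
    alt_key: str = "DV",
) -> list[SVRecord]:
    """Read SVs from a VCF v4.x file.

    SVLEN is taken from INFO (absolute value); supports are looked up first
    in the FORMAT fields of the first sample, then in INFO, under the
    configurable `ref_key`/`alt_key` names (Sniffles-style DR/DV defaults).
    """
    import pysam

    out: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svlen = rec.info.get("SVLEN")
            if svlen is None:
                svlen = 0
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            svlen = abs(int(svlen))

            def _support(key: str) -> int:
                if rec.samples and key in rec.samples[0]:
                    v = rec.samples[0][key]
                elif key in rec.info:
                    v = rec.info[key]
                else:
                    raise FormatError(
                        f"support key {key!r} absent from VCF record at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                if isinstance(v, (tuple, list)):
                    v = v[0]
                return int(v)

            out.append(
                SVRecord(rec.chrom, rec.pos, svlen, _support(ref_key), _support(alt_key))
            )
    return out


def write_sv_vcf(
    records: Sequence[SVRecord],
    lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write a minimal VCF v4.2 with SVLEN in INFO and DR/DV per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for sid, n in lengths.items():
            fh.write(f"##contig=<ID={sid},length={n}>\n")
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference support">\n')
        fh.write('##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.pos}\t.\tN\t<DEL>\t.\tPASS\t"
                f"SVTYPE=DEL;SVLEN={r.sv_len}\tDR:DV\t{r.ref_support}:{r.alt_support}\n"
            )


# ---------------------------------------------------------------------------
# linkage-map markers (TSV)

MARKER_COLUMNS = ["marker_id", "lg", "cm", "seq_id", "pos", "mapq"]


@dataclass
class MarkerRecord:
    """A linkage-map marker with optional assembly alignment."""

    marker_id: str
    lg: str
    cm: float
    aln_seq_id: str | None = None
    aln_pos: int | None = None
    mapq: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.cm) or self.cm < 0:
            raise FormatError(f"marker {self.marker_id}: invalid cM {self.cm}")
        if self.mapq is not None and not (0 <= self.mapq <= 60):
            raise FormatError(f"marker {self.marker_id}: MAPQ {self.mapq} out of [0,60]")

    @property
    def aligned(self) -> bool:
        return self.aln_seq_id is not None and self.aln_pos is not None


def read_marker_tsv(path: str | Path) -> list[MarkerRecord]:
    """Read a marker table with header ``marker_id lg cm [seq_id pos mapq]``."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "lg": str})
    for col in ("marker_id", "lg", "cm"):
        if col not in df.columns:
            raise FormatError(f"marker table missing column {col!r}")
    out: list[MarkerRecord] = []
    has_aln = all(c in df.columns for c in ("seq_id", "pos", "mapq"))
    for row in df.itertuples(index=False):
        if has_aln and isinstance(row.seq_id, str) and row.seq_id:
            out.append(
                MarkerRecord(
                    row.marker_id, row.lg, float(row.cm),
                    row.seq_id, int(row.pos), int(row.mapq),
                )
            )
        else:
            out.append(MarkerRecord(row.marker_id, row.lg, float(row.cm)))
    return out


def write_marker_tsv(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    rows = []
    for m in markers:
        rows.append(
            {
                "marker_id": m.marker_id,
                "lg": m.lg,
                "cm": m.cm,
                "seq_id": m.aln_seq_id if m.aligned else "",
                "pos": m.aln_pos if m.aligned else "",
                "mapq": m.mapq if m.mapq is not None else "",
            }
        )
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)
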