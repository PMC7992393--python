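"""Linkage-map integration: marker filtering, LG assignment, ordering.

Markers from a genetic map carry a linkage group (LG) and a cM position;
their alignments to the assembly carry a scaffold, a position and a MAPQ.
Markers aligned with MAPQ > 16 (strict) are retained; each scaffold is
assigned to the modal LG of its markers (with a conflict flag when the
runner-up LG holds more than 20% of them); scaffolds within an LG are
ordered by mean marker cM and oriented by the sign of the Spearman
correlation between cM and physical position (rho >= 0 means forward;
|rho| < 0.5 is reported as uncertain).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_core import MarkerRecord


@dataclass(frozen=True)
class LGAssignment:
    seq_id: str
    lg: str
    support_fraction: float
    n_markers: int
    conflicting: bool


@dataclass(frozen=True)
class ScaffoldPlacement:
    seq_id: str
    lg: str
    mean_cm: float
    orientation: str  # "+", "-", "uncertain", "unknown"
    rho: float | None
    n_markers: int


def filter_markers(
    markers: Sequence[MarkerRecord], min_mapq_exclusive: int = 16
) -> list[MarkerRecord]:
    """Retain aligned markers with MAPQ strictly above the threshold."""
    return [
        m
        for m in markers
        if m.aligned and m.mapq is not None and m.mapq > min_mapq_exclusive
    ]


def assign_lg(
    markers: Sequence[MarkerRecord], conflict_fraction: float = 0.20
) -> list[LGAssignment]:
    """Assign each scaffold to the modal LG of its retained markers.

    The assignment is invariant to marker order (counts only); a scaffold
    is flagged conflicting when its second-most-common LG exceeds
    `conflict_fraction` of its markers.
    """
    by_scaffold: dict[str, Counter] = {}
    for m in markers:
        if not m.aligned:
            continue
        by_scaffold.setdefault(m.aln_seq_id, Counter())[m.lg] += 1
    out: list[LGAssignment] = []
    for sid in sorted(by_scaffold):
        counts = by_scaffold[sid]
        n = sum(counts.values())
        # ties broken deterministically by LG label
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        lg, top = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0
        out.append(
            LGAssignment(sid, lg, top / n, n, second > conflict_fraction * n)
        )
    return out


def order_orient(
    markers: Sequence[MarkerRecord],
    lg: str,
    min_abs_rho: float = 0.5,
) -> list[ScaffoldPlacement]:
    """Order and orient the scaffolds of one linkage group.

    Scaffolds are sorted by the mean cM of their markers.  Orientation is
    the sign of the Spearman correlation between marker cM and physical
    position on the scaffold; |rho| below `min_abs_rho` is reported
    "uncertain", fewer than 2 markers "unknown".
    """
    per_scaffold: dict[str, list[MarkerRecord]] = {}
    for m in markers:
        if m.aligned and m.lg == lg:
            per_scaffold.setdefault(m.aln_seq_id, []).append(m)
    placements: list[ScaffoldPlacement] = []
    for sid, ms in per_scaffold.items():
        cms = np.array([m.cm for m in ms])
        mean_cm = float(np.mean(cms))
        if len(ms) < 2:
            placements.append(
                ScaffoldPlacement(sid, lg, mean_cm, "unknown", None, len(ms))
            )
            continue
        pos = np.array([m.aln_pos for m in ms], dtype=float)
        if np.all(cms == cms[0]) or np.all(pos == pos[0]):
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(cms, pos).statistic)
        if not np.isfinite(rho) or abs(rho) < min_abs_rho:
            orient = "uncertain"
        else:
            orient = "+" if rho >= 0 else "-"
        placements.append(
            ScaffoldPlacement(sid, lg, mean_cm, orient, rho if np.isfinite(rho) else None, len(ms))
        )
    placements.sort(key=lambda p: (p.mean_cm, p.seq_id))
    return placements


def write_agp(
    placements_by_lg: dict[str, Sequence[ScaffoldPlacement]],
    scaffold_lengths: dict[str, int],
    path,
    gap_len: int = 100,
) -> None:
    """AGP v2.1 pseudo-chromosomes: anchored scaffolds separated by fixed
    100-N map-evidence gaps; uncertain/unknown orientations written '?'."""
    orient_map = {"+": "+", "-": "-", "uncertain": "?", "unknown": "?"}
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for lg in sorted(placements_by_lg):
            pos = 1
            part = 1
            placements = placements_by_lg[lg]
            for i, pl in enumerate(placements):
                ln = scaffold_lengths[pl.seq_id]
                fh.write(
                    f"{lg}\t{pos}\t{pos + ln - 1}\t{part}\tW\t{pl.seq_id}\t1\t{ln}\t"
                    f"{orient_map[pl.orientation]}\n"
                )
                pos += ln
                part += 1
                if i < len(placements) - 1:
                    fh.write(
                        f"{lg}\t{pos}\t{pos + gap_len - 1}\t{part}\tN\t{gap_len}\t"
                        f"scaffold\tyes\tmap\n"
                    )
                    pos += gap_len
                    part += 1
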