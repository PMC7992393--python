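"""Coverage-based assembly QC and the SV-support assembly-error filter.

Low-accuracy scaffolds are identified from short-read coverage: median
depth per 1-kb non-overlapping window, GC-normalized by binned median
ratio, then any scaffold with more than 70% of its windows deviating more
than 2 SD from the assembly-wide mean is flagged.  Separately, structural
variant calls of at least 50 bp whose reference-allele support ratio is
below 0.2 mark likely base-level assembly errors.

Threshold semantics (documented, configurable): the window-fraction and
support-ratio comparisons are strict (> 0.70, < 0.2); "2 SD above or
below the mean" means strictly outside the band; mean and SD are computed
assembly-wide, not per scaffold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_core import DepthTrack, SVRecord, gc_fraction


@dataclass(frozen=True)
class QCWindow:
    seq_id: str
    start: int
    end: int
    gc: float | None
    median_depth_raw: float
    median_depth_norm: float | None = None


@dataclass(frozen=True)
class ScaffoldFlag:
    seq_id: str
    frac_outlier_windows: float
    flagged: bool


def window_medians(
    track: DepthTrack, seq: str, window: int = 1000
) -> list[QCWindow]:
    """Median depth per non-overlapping window tiled from position 0.

    The last window may be shorter; window GC comes from the sequence.
    """
    n = len(track.depths)
    if n < 1:
        warnings.warn(f"scaffold {track.seq_id} shorter than 1 bp, skipped", stacklevel=2)
        return []
    if len(seq) != n:
        raise ValueError(
            f"depth track ({n}) and sequence ({len(seq)}) lengths differ for {track.seq_id}"
        )
    out: list[QCWindow] = []
    for s in range(0, n, window):
        e = min(s + window, n)
        out.append(
            QCWindow(
                track.seq_id, s, e,
                gc_fraction(seq[s:e]),
                float(np.median(track.depths[s:e])),
            )
        )
    return out


def gc_normalize(
    windows: Sequence[QCWindow], bin_width: float = 0.02, min_bin_windows: int = 10
) -> list[QCWindow]:
    """Fill `median_depth_norm` by binned GC median ratio.

    Windows are binned by GC in `bin_width` steps; each populated bin
    (>= `min_bin_windows` windows and non-zero median) gets the factor
    global_median / bin_median, where the global median is taken over the
    windows of populated bins.  Sparse bins inherit the factor of the
    nearest populated bin; windows without defined GC get factor 1.
    """
    if not windows:
        raise ValueError("no windows to normalize")
    raw = np.array([w.median_depth_raw for w in windows])
    if np.all(raw == 0):
        raise ValueError("all window depths are zero")
    bins = np.array(
        [int(w.gc / bin_width) if w.gc is not None else -1 for w in windows]
    )
    factors: dict[int, float] = {}
    populated: list[int] = []
    for b in sorted(set(bins[bins >= 0])):
        vals = raw[bins == b]
        if len(vals) >= min_bin_windows and np.median(vals) > 0:
            populated.append(b)
    if populated:
        pop_mask = np.isin(bins, populated)
        global_med = float(np.median(raw[pop_mask]))
        for b in populated:
            factors[b] = global_med / float(np.median(raw[bins == b]))
    out: list[QCWindow] = []
    for w, b in zip(windows, bins):
        if b in factors:
            f = factors[b]
        elif populated and b >= 0:
            nearest = min(populated, key=lambda p: (abs(p - b), p))
            f = factors[nearest]
        else:
            f = 1.0
        out.append(replace(w, median_depth_norm=w.median_depth_raw * f))
    return out


def flag_low_accuracy(
    windows: Sequence[QCWindow],
    frac_threshold: float = 0.70,
    sd_mult: float = 2.0,
) -> list[ScaffoldFlag]:
    """Flag scaffolds whose outlier-window fraction exceeds the threshold.

    A window is an outlier when its normalized median deviates strictly
    more than `sd_mult` SD from the assembly-wide mean of normalized
    medians.  A scaffold is flagged iff its outlier fraction is strictly
    greater than `frac_threshold`.  With SD = 0 any deviating window is
    an outlier.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to define an SD")
    vals = np.array(
        [
            w.median_depth_norm if w.median_depth_norm is not None else w.median_depth_raw
            for w in windows
        ]
    )
    mean = float(np.mean(vals))
    sd = float(np.std(vals))
    outlier = np.abs(vals - mean) > sd_mult * sd
    flags: list[ScaffoldFlag] = []
    ids: list[str] = []
    for w in windows:
        if w.seq_id not in ids:
            ids.append(w.seq_id)
    sids = np.array([w.seq_id for w in windows])
    for sid in ids:
        m = sids == sid
        frac = float(np.mean(outlier[m]))
        flags.append(ScaffoldFlag(sid, frac, frac > frac_threshold))
    return flags


def filter_sv_errors(
    svs: Sequence[SVRecord], min_size: int = 50, max_ref_ratio: float = 0.2
) -> list[SVRecord]:
    """Assembly-error calls: length >= `min_size` and reference-support
    ratio strictly below `max_ref_ratio`.

    Records with zero total support are excluded with a warning.
    """
    errors: list[SVRecord] = []
    for sv in svs:
        if sv.sv_len < 0 or sv.ref_support < 0 or sv.alt_support < 0:
            raise ValueError("negative SV fields")
        total = sv.ref_support + sv.alt_support
        if total == 0:
            warnings.warn(
                f"SV at {sv.seq_id}:{sv.pos} has zero total support, excluded",
                stacklevel=2,
            )
            continue
        if sv.sv_len >= min_size and sv.ref_support / total < max_ref_ratio:
            errors.append(sv)
    return errors
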