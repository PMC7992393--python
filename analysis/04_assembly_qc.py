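#!/usr/bin/env python
"""Coverage QC of the scaffold set and SV-based error filtering.

Computes 1-kb window medians from the simulated depth track,
GC-normalizes them, flags scaffolds with >70% of windows beyond 2 SD of
the assembly-wide mean, and filters the SV call set for likely assembly
errors (>= 50 bp, reference-support ratio < 0.2).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oysterkit.asm_qc import (
    filter_sv_errors,
    flag_low_accuracy,
    gc_normalize,
    window_medians,
)
from oysterkit.io_core import read_bedgraph, read_fasta, read_sv_vcf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    scaffolds = read_fasta(args.sim_dir / "scaffolds.fasta")
    lengths = {r.id: len(r.seq) for r in scaffolds}
    seqs = {r.id: r.seq for r in scaffolds}
    tracks = read_bedgraph(args.sim_dir / "depth.bedgraph", lengths)
    truth = json.loads((args.sim_dir / "truth.json").read_text())

    windows = []
    for sid, tr in tracks.items():
        windows += window_medians(tr, seqs[sid])
    windows = gc_normalize(windows)
    flags = flag_low_accuracy(windows)
    pd.DataFrame(
        [
            {"seq_id": f.seq_id, "frac_outlier_windows": round(f.frac_outlier_windows, 3),
             "flagged": f.flagged}
            for f in flags
        ]
    ).to_csv(args.out / "qc_flags.tsv", sep="\t", index=False)

    flagged = {f.seq_id for f in flags if f.flagged}
    junk = set(truth["junk_scaffold_ids"])
    print(f"{len(windows)} windows over {len(flags)} scaffolds; "
          f"flagged {sorted(flagged)} (planted junk: {sorted(junk)})")

    svs = read_sv_vcf(args.sim_dir / "svs.vcf")
    errors = filter_sv_errors(svs)
    err_keys = {(e.seq_id, e.pos) for e in errors}
    labels = truth["sv_error_labels"]
    planted = {(s.seq_id, s.pos) for s, l in zip(svs, labels) if l}
    pd.DataFrame(
        [{"seq_id": e.seq_id, "pos": e.pos, "sv_len": e.sv_len,
          "ref_support": e.ref_support, "alt_support": e.alt_support}
         for e in errors]
    ).to_csv(args.out / "sv_errors.tsv", sep="\t", index=False)
    print(f"SV error filter: {len(errors)} of {len(svs)} calls flagged as "
          f"assembly errors; planted errors recovered "
          f"{len(err_keys & planted)}/{len(planted)}")


if __name__ == "__main__":
    main()
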