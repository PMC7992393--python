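#!/usr/bin/env python
"""Build the synthetic study genome and all derived inputs.

Generates a 3-chromosome diploid-like assembly with haplotig duplicates,
gene/repeat annotation truth, GC-biased short-read depth over the
scaffold set (chromosomes plus two planted low-accuracy scaffolds),
linkage-map markers, and an SV call set with planted assembly errors.
Everything downstream (02-06) reads from the output directory.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from oysterkit.io_core import (
    SeqRecord,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_marker_tsv,
    write_sv_vcf,
)
from oysterkit.simulate import (
    AssemblyConfig,
    random_seq,
    simulate_assembly,
    simulate_depth,
    simulate_markers,
    simulate_svs,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    cfg = AssemblyConfig(n_chromosomes=3, chrom_len=400_000)
    contigs, truth = simulate_assembly(cfg, rng)
    write_fasta(contigs, args.out / "contigs.fasta")
    write_bed(truth.features, args.out / "features.bed")

    # scaffold set: chromosomes plus two junk (low-accuracy) scaffolds
    chroms = []
    for cid in truth.chrom_lengths:
        parts = [c.seq for c in contigs if c.id.startswith(cid + "_")]
        chroms.append(SeqRecord(cid, "".join(parts)))
    junk_ids = ["unplaced_junk1", "unplaced_junk2"]
    scaffolds = chroms + [SeqRecord(j, random_seq(rng, 20_000, 0.33)) for j in junk_ids]
    write_fasta(scaffolds, args.out / "scaffolds.fasta")
    tracks = simulate_depth(
        scaffolds, rng, mean_depth=30, gc_bias_slope=0.8, junk_ids=junk_ids
    )
    write_bedgraph(tracks, args.out / "depth.bedgraph")

    markers, scaffold_truth = simulate_markers(
        truth.chrom_lengths, rng, cm_noise_sd=0.5, mapq_low_frac=0.1
    )
    write_marker_tsv(markers, args.out / "markers.tsv")

    svs, sv_labels = simulate_svs(truth.chrom_lengths, rng)
    write_sv_vcf(svs, truth.chrom_lengths, args.out / "svs.vcf")

    meta = {
        "seed": args.seed,
        "chrom_lengths": truth.chrom_lengths,
        "haplotig_ids": [h.contig_id for h in truth.haplotigs],
        "junk_scaffold_ids": junk_ids,
        "sv_error_labels": sv_labels,
        "scaffold_truth": [asdict(s) for s in scaffold_truth],
    }
    (args.out / "truth.json").write_text(json.dumps(meta, indent=2))

    n_hap = len(truth.haplotigs)
    print(f"wrote {len(contigs)} contigs ({n_hap} planted haplotigs), "
          f"{len(scaffolds)} scaffolds ({len(junk_ids)} junk), "
          f"{len(truth.features)} features, {len(markers)} markers, {len(svs)} SVs "
          f"to {args.out}")


if __name__ == "__main__":
    main()
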