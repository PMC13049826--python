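#!/usr/bin/env python
"""Build the synthetic study locus and export its reference and features.

Writes the 77 kb reference FASTA, a BED track of exons / amplicons / the
truth structural variant, and a panel summary table, then prints the
assay geometry it produced.
"""

import argparse
from pathlib import Path

import pandas as pd

from haplotile.io import write_fasta, write_locus_bed, write_tsv
from haplotile.pcr import simulate_amplicon
from haplotile.simulate import build_reference_locus


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/locus"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    locus = build_reference_locus(seed=args.seed)
    write_fasta({locus.reference.name: locus.reference.sequence},
                args.outdir / "reference.fasta")
    write_locus_bed(locus, args.outdir / "locus_features.bed")

    rows = []
    for amp in locus.panel:
        product = simulate_amplicon(locus.reference.sequence, amp.pair,
                                    locus.lr_max_product)
        rows.append(dict(amplicon=amp.name, start=amp.start, end=amp.end,
                         product_bp=product.length,
                         forward=amp.pair.forward, reverse=amp.pair.reverse))
    df = pd.DataFrame(rows)
    write_tsv(df, args.outdir / "amplicon_panel.tsv")

    overlaps = locus.panel.overlaps
    print(f"locus: {locus.reference.length} bp, 15 exons, CDS "
          f"{locus.transcript.coding_length()} bp")
    print(df.to_string(index=False))
    print(f"overlaps between adjacent amplicons: {overlaps} bp")
    sv = locus.sv_truth
    print(f"truth SV: {len(sv.ref)} bp deleted, {len(sv.alt)} bp inserted "
          f"(g.{sv.pos}_{sv.end})")


if __name__ == "__main__":
    main()
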