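#!/usr/bin/env python
"""Filter the simulated DE table and bin the kept genes by fold change.

Keeps genes with p < 0.05 and fold change > 1.5 or < 1/1.5, then tabulates
them into fold-change ranges (up and down separately).
"""
import argparse
from pathlib import Path

from mscc.de import fc_histogram, filter_de, read_de_tsv, write_de_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/de_filtered.tsv"))
    args = ap.parse_args()

    table = read_de_tsv(args.simdir / "de.tsv")
    kept = filter_de(table)
    write_de_tsv(kept, args.out)
    n_up = int((kept["direction"] == "up").sum())
    n_down = int((kept["direction"] == "down").sum())
    print(f"{len(kept)} / {len(table)} genes pass (p<0.05, |FC|>1.5): "
          f"{n_up} up, {n_down} down -> {args.out}")

    edges = [0.0, 1 / 3, 0.5, 1 / 1.5, 1.5, 2.0, 3.0, 1000.0]
    hist = fc_histogram(kept, edges)
    hist = hist[hist["n_total"] > 0]
    print("fold-change bins:")
    for r in hist.itertuples(index=False):
        print(f"  [{r.bin_left:7.4f}, {r.bin_right:8.4f}): "
              f"{r.n_up} up, {r.n_down} down")


if __name__ == "__main__":
    main()
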