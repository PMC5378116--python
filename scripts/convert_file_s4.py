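#!/usr/bin/env python
"""Convert the supplementary Drosophila loci table to the iimcoal TSV dialect.

The published analysis distributes its processed loci (Drosophila simulans /
D. melanogaster pairwise segregating-site counts with relative mutation
rates, ~30k loci) as a supplementary file whose exact column layout is not
described in the article text.  This converter therefore takes the column
names (or 0-based positions) on the command line, so it can be pointed at
whichever layout the downloaded file has, and emits the documented
``locus_id  state  s  rel_rate  order_index`` tab-separated table that
:func:`iimcoal.read_loci` consumes.

The SHA-256 of the input file is printed and stored alongside the output
(``<out>.sha256``), so a converted table can always be traced back to the
exact supplementary file it came from.

Example:

    python scripts/convert_file_s4.py FileS4.txt data/drosophila_loci.tsv \
        --state-col state --s-col s --rate-col relrate --sep whitespace
"""

from __future__ import annotations

import argparse
import hashlib
import pathlib
import sys

import pandas as pd


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("infile", type=pathlib.Path)
    ap.add_argument("outfile", type=pathlib.Path)
    ap.add_argument("--state-col", default="state",
                    help="column with the sampling configuration (1/2/3)")
    ap.add_argument("--s-col", default="s",
                    help="column with the segregating-site count")
    ap.add_argument("--rate-col", default=None,
                    help="column with the relative mutation rate (optional)")
    ap.add_argument("--sep", default="whitespace",
                    help="field separator: 'whitespace', 'tab' or 'comma'")
    ap.add_argument("--no-header", action="store_true",
                    help="the input has no header row; use 0-based positions")
    args = ap.parse_args(argv)

    digest = hashlib.sha256(args.infile.read_bytes()).hexdigest()
    sep = {"whitespace": r"\s+", "tab": "\t", "comma": ","}[args.sep]
    df = pd.read_csv(args.infile, sep=sep,
                     header=None if args.no_header else 0)

    def col(key):
        if args.no_header:
            return df.iloc[:, int(key)]
        return df[key]

    out = pd.DataFrame(
        {
            "locus_id": [f"S4_{i:06d}" for i in range(len(df))],
            "state": col(args.state_col).astype(int),
            "s": col(args.s_col).astype(int),
            "rel_rate": col(args.rate_col).astype(float)
            if args.rate_col is not None
            else 1.0,
            "order_index": range(len(df)),
        }
    )
    if not out["state"].isin((1, 2, 3)).all():
        raise SystemExit("state column contains values outside {1, 2, 3}")
    args.outfile.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.outfile, sep="\t", index=False)
    args.outfile.with_suffix(args.outfile.suffix + ".sha256").write_text(
        f"{digest}  {args.infile.name}\n"
    )
    print(f"wrote {len(out)} loci to {args.outfile}")
    print(f"input sha256: {digest}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
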