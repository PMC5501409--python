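"""QTL summarization: 5-cM merging and stability classification.

Merges the significant MTAs into QTL by single-linkage chaining of peak
positions closer than 5 cM (within trait and chromosome), classifies each
QTL's stability across families and N levels from its members' model
provenance, and cross-tabulates MTA counts by scope.  Writes the QTL table
and the cross-tab under results/qtl/.
"""

import argparse
from pathlib import Path

import pandas as pd

from abqtl import io, qtlsum


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--gwas", type=Path, default=Path("results/gwas"))
    ap.add_argument("--out", type=Path, default=Path("results/qtl"))
    args = ap.parse_args()

    mta = io.read_table(args.gwas / "mta.tsv", index_col=None)
    gmap = io.read_map(args.sim / "map.tsv")
    qtls = qtlsum.merge_mtas(mta, gmap, window_cm=5.0)
    cross, table = qtlsum.summary_tables(qtls, mta)

    io.write_table(table, args.out / "qtl.tsv", args.seed, index=False)
    io.write_table(cross, args.out / "mta_crosstab.tsv", args.seed)

    pd.set_option("display.width", 220)
    print(f"{len(qtls)} QTL from {len(mta)} MTAs (merge window 5 cM)")
    print("\nMTA counts by N scope x family scope:")
    print(cross.to_string())
    print("\nQTL table:")
    cols = ["qtl_name", "trait", "chromosome", "peak_snp", "position_cM", "range_cM",
            "n_mtas", "exotic_effect", "r2_adj", "family_class", "n_class"]
    print(table[cols].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
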