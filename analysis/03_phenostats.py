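"""Phenotype analysis: adjusted means, trait ratios, heritability, correlations.

Computes least-squares line means within and across N levels, the N0/N1
trait ratios, Table-style descriptive statistics with entry-mean
heritabilities from ANOVA variance components, trait correlations and the
fixed-effects ANOVA per trait.  Writes tables under results/pheno/.
"""

import argparse
from pathlib import Path

import pandas as pd

from abqtl import io, phenostats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/pheno"))
    args = ap.parse_args()

    table = io.read_phenotypes(args.sim / "phenotypes.tsv")
    traits = sorted(pd.unique(table["trait"]))
    n_levels = sorted(pd.unique(table["n_level"]))

    means = {"across": phenostats.adjusted_line_means(table)}
    for nl in n_levels:
        means[nl] = phenostats.adjusted_line_means(table, scope=nl)
    lo, hi = n_levels
    for t in traits:
        means["across"][f"{t}_ratio"] = phenostats.trait_ratio(means[lo][t], means[hi][t])

    rows = []
    for t in traits:
        for label, nl in [("across", None)] + [(nl, nl) for nl in n_levels]:
            vec = (means["across"] if nl is None else means[nl])[t].dropna()
            stats_ = phenostats.descriptive_stats(vec)
            vc = phenostats.variance_components(
                table, t, "across" if nl is None else "within", n_level=nl
            )
            h2 = phenostats.heritability(vc, "across" if nl is None else "within")
            rows.append({"trait": t, "n_level": label, **stats_, "h2_percent": 100 * h2})
    summary = pd.DataFrame(rows)
    corr = phenostats.pearson_correlations(means["across"])

    io.write_table(summary, args.out / "trait_summary.tsv", args.seed, index=False)
    io.write_table(corr, args.out / "correlations.tsv", args.seed)
    for key, df in means.items():
        io.write_table(df, args.out / f"line_means_{key}.tsv", args.seed)
    for t in traits:
        io.write_table(phenostats.anova(table, t, "across"), args.out / f"anova_{t}.tsv", args.seed)

    pd.set_option("display.width", 160)
    print("trait summary (line-mean scale):")
    print(summary.round(2).to_string(index=False))
    print("\nratio means (N0/N1):",
          {f"{t}_ratio": round(float(means['across'][f'{t}_ratio'].mean()), 2) for t in traits})
    print("\ncorrelations between across-N line means:")
    print(corr.round(2).to_string())


if __name__ == "__main__":
    main()
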