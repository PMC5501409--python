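"""Simulate the SW84-style tri-parental BC2F4 population.

Generates the study conditions end to end: a 21-chromosome map with ~4,096
evenly spaced SNPs, two families (154 + 205 lines) from two backcrosses and
three selfings, 2% missing calls, three planted grain-quality QTL (GPC +0.70
on 6B, GH -8.98 on 5D, SED +7.31 on 4B, exotic-effect scale) and phenotypes
over three environments x two N levels.  Writes genotype, family, map and
phenotype tables under results/sim/.
"""

import argparse
from pathlib import Path

import numpy as np

from abqtl import io, simpop
from abqtl.pipeline import _resolve_qtl, _simulate_phenotypes_from_config, default_sw84_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    ap.add_argument("--n-snps", type=int, default=4096)
    args = ap.parse_args()

    cfg = default_sw84_config(seed=args.seed, n_snps=args.n_snps)
    sim = cfg.simulate
    gmap = simpop.uniform_map(sim["n_snps"], chromosome_length_cM=sim["chromosome_length_cM"])
    rng = np.random.default_rng(args.seed)
    pop = simpop.simulate_population(
        simpop.CrossingScheme(**sim["scheme"]), gmap, rng,
        missing_rate=sim["missing_rate"],
        divergent_fraction=sim["divergent_fraction"], full=True,
    )
    genotypes, families = pop.genotypes, pop.families
    planted = [_resolve_qtl(q, gmap) for q in sim["qtl"]]
    phenotypes = _simulate_phenotypes_from_config(
        genotypes, families, planted, sim["pheno"], rng
    )

    cfgd = cfg.as_dict()
    io.write_map(gmap, args.out / "map.tsv", args.seed, cfgd)
    io.write_genotypes(genotypes, args.out / "genotypes.tsv", args.seed, cfgd)
    io.write_genotypes(pop.raw_alleles, args.out / "raw_alleles.tsv", args.seed, cfgd)
    io.write_genotypes(pop.parent_raw, args.out / "parents_raw.tsv", args.seed, cfgd)
    io.write_families(families, args.out / "families.tsv", args.seed, cfgd)
    io.write_phenotypes(phenotypes, args.out / "phenotypes.tsv", args.seed, cfgd)
    truth = [
        {"trait": q.trait, "snp_id": q.snp_id, "exotic_effect": 2 * q.additive_effect}
        for q in planted
    ]
    import pandas as pd

    io.write_table(pd.DataFrame(truth), args.out / "planted_qtl.tsv", args.seed, cfgd, index=False)

    f0, f1, f2 = simpop.expected_genotype_frequencies(simpop.SW84_SCHEME)
    print(f"simulated {genotypes.shape[0]} lines x {genotypes.shape[1]} SNPs -> {args.out}")
    print(f"expected genotype-class frequencies: {f0:.6f} : {f1:.6f} : {f2:.6f}")
    arr = genotypes.to_numpy()
    obs = [np.nanmean(arr == k) / np.nanmean(~np.isnan(arr)) for k in (0, 1, 2)]
    print(f"observed:                            {obs[0]:.6f} : {obs[1]:.6f} : {obs[2]:.6f}")
    print(f"mean per-line exotic-allele proportion: {np.nanmean(arr) / 2:.4f} (theory 0.125)")


if __name__ == "__main__":
    main()
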