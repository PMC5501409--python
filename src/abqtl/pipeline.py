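"""End-to-end orchestration: simulate → qc → phenostats → relatedness → gwas → summarize.

A run is driven by a :class:`RunConfig` (typically parsed from a YAML file):
inputs either come from TSV files (genotypes, map, families, phenotypes) or
from the built-in population simulator.  Each stage writes its tables into
the run directory, a combined log records the QC funnel and stage timings,
and a machine-readable manifest captures version, seed and parameters, so
that re-running an identical config reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, genoqc, gwas, io, phenostats, qtlsum, relatedness, simpop

__all__ = ["RunConfig", "run_pipeline", "load_config", "default_sw84_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file inputs or simulator settings)."""

    output_dir: str = "abqtl_run"
    seed: int = 0
    # file inputs (all four required together); ignored when simulate is set
    genotypes: str | None = None
    genetic_map: str | None = None
    families: str | None = None
    phenotypes: str | None = None
    simulate: dict | None = None
    qc: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    qtl: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.simulate is None:
            paths = {
                "genotypes": self.genotypes,
                "genetic_map": self.genetic_map,
                "families": self.families,
                "phenotypes": self.phenotypes,
            }
            missing = [k for k, v in paths.items() if v is None]
            if missing:
                raise ValueError(f"config lacks simulator settings and input paths: {missing}")
            absent = [v for v in paths.values() if not Path(v).exists()]
            if absent:
                raise FileNotFoundError(f"input path(s) do not exist: {absent}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def default_sw84_config(output_dir: str = "abqtl_run", seed: int = 0, n_snps: int = 4096) -> RunConfig:
    """The SW84-preset simulation config: two families (154 + 205 lines),
    ~4,096 mapped SNPs on 21 chromosomes, three planted QTL with effects on
    the scale reported for grain-quality loci, three environments and two N
    levels."""
    return RunConfig(
        output_dir=output_dir,
        seed=seed,
        simulate={
            "n_snps": n_snps,
            "chromosome_length_cM": 160.0,
            "missing_rate": 0.02,
            # fraction of assayed loci at which the recurrent parents carry
            # different array alleles (donor heterozygous), giving the raw
            # genotype states their family-differentiating structure
            "divergent_fraction": 0.65,
            "scheme": {},
            "qtl": [
                {"trait": "GPC", "chromosome": "6B", "position_cM": 57.0, "exotic_effect": 0.70},
                {"trait": "GH", "chromosome": "5D", "position_cM": 52.0, "exotic_effect": -8.98},
                {"trait": "SED", "chromosome": "4B", "position_cM": 62.0, "exotic_effect": 7.31},
            ],
            # per-trait means, design effects and variance components chosen to
            # reproduce grain-quality scales: GPC in % (entry-mean SD ~0.65,
            # h2 ~0.6), GH in % (major 5D locus plus polygenic background,
            # h2 ~0.9), SED in ml (h2 ~0.5); N effects are half the observed
            # low-to-high nitrogen mean shifts.
            "pheno": {
                "per_trait": {
                    "GPC": {
                        "mean": 12.54,
                        "environment_effects": {"D04": 0.0, "H04": 0.3, "H05": -0.3},
                        "n_level_effects": {"N0": -1.16, "N1": 1.16},
                        "variances": {"v_g": 0.26, "v_gxe": 0.10, "v_gxn": 0.05, "v_r": 0.60},
                    },
                    "GH": {
                        "mean": 53.95,
                        "environment_effects": {"D04": 0.0, "H04": 1.0, "H05": -1.0},
                        "n_level_effects": {"N0": -1.31, "N1": 1.31},
                        "variances": {"v_g": 8.0, "v_gxe": 1.0, "v_gxn": 0.5, "v_r": 3.0},
                    },
                    "SED": {
                        "mean": 36.23,
                        "environment_effects": {"D04": 0.0, "H04": 2.0, "H05": -2.0},
                        "n_level_effects": {"N0": -6.82, "N1": 6.82},
                        "variances": {"v_g": 7.5, "v_gxe": 6.0, "v_gxn": 4.0, "v_r": 45.0},
                    },
                },
            },
        },
    )


def simulate_study(
    sim: dict, seed: int, gmap: simpop.GeneticMap | None = None
) -> tuple[simpop.SimulatedPopulation, pd.DataFrame, list[simpop.PlantedQtl]]:
    """Simulate one study realization from a ``simulate`` config block.

    Returns the population, the long-format phenotype table and the planted
    QTL (with positions resolved to mapped SNPs).  A pre-built map may be
    passed to avoid rebuilding it across repeated runs.
    """
    if gmap is None:
        gmap = simpop.uniform_map(
            int(sim.get("n_snps", 4096)),
            chromosome_length_cM=float(sim.get("chromosome_length_cM", 160.0)),
        )
    rng = np.random.default_rng(seed)
    pop = simpop.simulate_population(
        simpop.CrossingScheme(**sim.get("scheme", {})),
        gmap,
        rng,
        missing_rate=float(sim.get("missing_rate", 0.0)),
        divergent_fraction=float(sim.get("divergent_fraction", 0.0)),
        full=True,
    )
    planted = [_resolve_qtl(q, gmap) for q in sim.get("qtl", [])]
    phenotypes = _simulate_phenotypes_from_config(
        pop.genotypes, pop.families, planted, sim.get("pheno", {}), rng
    )
    return pop, phenotypes, planted


def _simulate_phenotypes_from_config(genotypes, families, planted, pheno_cfg, rng):
    """Build phenotypes from either a shared or a per-trait pheno config block."""
    if "per_trait" in pheno_cfg:
        parts = []
        for trait, tc in pheno_cfg["per_trait"].items():
            model = simpop.PhenoModelConfig(
                trait_means={trait: float(tc.get("mean", 0.0))},
                environment_effects=tc.get(
                    "environment_effects", {"D04": 0.0, "H04": 0.4, "H05": -0.4}
                ),
                n_level_effects=tc.get("n_level_effects", {"N0": -1.0, "N1": 1.0}),
                **tc.get("variances", {}),
            )
            qtl = [q for q in planted if q.trait == trait]
            parts.append(
                simpop.simulate_phenotypes(genotypes, qtl, model, rng, families=families)
            )
        return pd.concat(parts, ignore_index=True)
    model = simpop.PhenoModelConfig(
        trait_means=pheno_cfg.get("trait_means", {"trait": 0.0}),
        environment_effects=pheno_cfg.get(
            "environment_effects", {"D04": 0.0, "H04": 0.4, "H05": -0.4}
        ),
        n_level_effects=pheno_cfg.get("n_level_effects", {"N0": -1.0, "N1": 1.0}),
        **pheno_cfg.get("variances", {}),
    )
    return simpop.simulate_phenotypes(genotypes, planted, model, rng, families=families)


def _resolve_qtl(spec: dict, gmap: simpop.GeneticMap) -> simpop.PlantedQtl:
    if "snp_id" in spec:
        snp = spec["snp_id"]
    else:
        on_chrom = gmap.chromosomes == spec["chromosome"]
        if not on_chrom.any():
            raise KeyError(f"chromosome {spec['chromosome']!r} not on map")
        pos = gmap.positions[on_chrom]
        ids = gmap.snp_ids[on_chrom]
        snp = str(ids[np.argmin(np.abs(pos - float(spec["position_cM"])))])
    if "additive_effect" in spec:
        a = float(spec["additive_effect"])
    else:
        a = float(spec["exotic_effect"]) / 2.0
    return simpop.PlantedQtl(
        snp_id=snp,
        trait=spec["trait"],
        additive_effect=a,
        families=frozenset(spec["families"]) if spec.get("families") else None,
        n_levels=frozenset(spec["n_levels"]) if spec.get("n_levels") else None,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order; returns the run directory.

    Stage failure raises with a stage-tagged message; artifacts written up to
    that point are retained.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the scientific parameters only, so identical configs written to
    # different directories produce byte-identical artifacts
    cfg = {k: v for k, v in config.as_dict().items() if k != "output_dir"}
    seed = config.seed
    log: list[str] = [f"abqtl {__version__} run, seed {seed}"]
    t0 = time.time()

    def _stage(name):
        log.append(f"[{time.time() - t0:7.1f}s] stage: {name}")

    def _fail(stage, exc):
        (outdir / "run.log").write_text("\n".join(log) + f"\nFAILED in {stage}: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate or load -------------------------------------------------
    try:
        _stage("inputs")
        if config.simulate is not None:
            sim = config.simulate
            gmap = simpop.uniform_map(
                int(sim.get("n_snps", 4096)),
                chromosome_length_cM=float(sim.get("chromosome_length_cM", 160.0)),
            )
            scheme = simpop.CrossingScheme(**sim.get("scheme", {}))
            rng = np.random.default_rng(seed)
            pop = simpop.simulate_population(
                scheme,
                gmap,
                rng,
                missing_rate=float(sim.get("missing_rate", 0.0)),
                divergent_fraction=float(sim.get("divergent_fraction", 0.0)),
                full=True,
            )
            genotypes, families = pop.genotypes, pop.families
            raw_states, parent_raw = pop.raw_alleles, pop.parent_raw
            planted = [_resolve_qtl(q, gmap) for q in sim.get("qtl", [])]
            pheno_cfg = sim.get("pheno", {})
            phenotypes = _simulate_phenotypes_from_config(
                genotypes, families, planted, pheno_cfg, rng
            )
            io.write_map(gmap, outdir / "map.tsv", seed, cfg)
            io.write_genotypes(genotypes, outdir / "genotypes.tsv", seed, cfg)
            io.write_genotypes(raw_states, outdir / "raw_alleles.tsv", seed, cfg)
            io.write_families(families, outdir / "families.tsv", seed, cfg)
            io.write_phenotypes(phenotypes, outdir / "phenotypes.tsv", seed, cfg)
            log.append(f"simulated {genotypes.shape[0]} lines x {genotypes.shape[1]} SNPs")
        else:
            gmap = io.read_map(config.genetic_map)
            genotypes = io.read_genotypes(config.genotypes)
            families = io.read_families(config.families)
            phenotypes = io.read_phenotypes(config.phenotypes)
            raw_states, parent_raw = genotypes, None
    except Exception as exc:  # noqa: BLE001
        _fail("inputs", exc)

    # --- qc ---------------------------------------------------------------
    try:
        _stage("qc")
        qc_cfg = config.qc
        expected = simpop.expected_genotype_frequencies(
            n_backcrosses=int(qc_cfg.get("n_backcrosses", 2)),
            n_selfings=int(qc_cfg.get("n_selfings", 3)),
        )
        alpha = float(qc_cfg.get("alpha", 0.05))
        non_failed = genoqc.filter_failure_rate(
            genotypes, float(qc_cfg.get("max_missing_fraction", 1.0))
        )
        seg = genoqc.segregation_test_matrix(non_failed, expected, alpha)
        funnel: list[str] = [f"scored: {genotypes.shape[1]}",
                             f"non-failed: {non_failed.shape[1]}"]
        informative = genoqc.informative_set(
            non_failed, families, gmap, test_results=seg,
            states=raw_states[non_failed.columns], log=funnel,
        )
        log.extend("qc funnel " + s for s in funnel)
        qc_report = seg.copy()
        qc_report.insert(
            0, "polymorphism",
            genoqc.classify_polymorphism(raw_states[non_failed.columns], families),
        )
        qc_report["informative"] = qc_report.index.isin(informative.columns)
        io.write_table(qc_report, outdir / "qc_report.tsv", seed, cfg)
        imputed = genoqc.mni_impute(informative)
        io.write_genotypes(imputed, outdir / "genotypes_informative_imputed.tsv", seed, cfg)
        exotic = genoqc.exotic_genome_proportion(informative)
        io.write_table(exotic.to_frame(), outdir / "exotic_proportion.tsv", seed, cfg)
        log.append(
            f"mean exotic-genome proportion {exotic.mean():.3f} "
            f"(range {exotic.min():.3f}-{exotic.max():.3f})"
        )
    except Exception as exc:  # noqa: BLE001
        _fail("qc", exc)

    # --- phenostats -------------------------------------------------------
    try:
        _stage("phenostats")
        traits = sorted(pd.unique(phenotypes["trait"]))
        n_levels = sorted(pd.unique(phenotypes["n_level"]))
        means = {"across": phenostats.adjusted_line_means(phenotypes)}
        for nl in n_levels:
            means[nl] = phenostats.adjusted_line_means(phenotypes, scope=nl)
        ratio_traits = []
        if len(n_levels) == 2:
            lo, hi = n_levels
            for t in traits:
                means["across"][f"{t}_ratio"] = phenostats.trait_ratio(
                    means[lo][t], means[hi][t]
                )
                ratio_traits.append(f"{t}_ratio")
        summary_rows = []
        for t in traits + ratio_traits:
            scopes = (
                [("across", "across", None)]
                if t in ratio_traits
                else [("across", "across", None)] + [(nl, "within", nl) for nl in n_levels]
            )
            for label, model, nl in scopes:
                col = means["across" if label == "across" else nl]
                vec = col[t].dropna() if t in col else None
                if vec is None or len(vec) < 2:
                    continue
                stats_ = phenostats.descriptive_stats(vec)
                vc_model = "across" if (model == "across" and t not in ratio_traits) else "within"
                vc = phenostats.variance_components(phenotypes, t, vc_model, n_level=nl) \
                    if t not in ratio_traits else _ratio_vc(phenotypes, means, t, lo, hi)
                h2 = phenostats.heritability(vc, "across" if vc_model == "across" else "within")
                summary_rows.append(
                    {"trait": t, "n_level": label, **stats_, "h2_percent": 100.0 * h2}
                )
        summary = pd.DataFrame(summary_rows)
        io.write_table(summary, outdir / "trait_summary.tsv", seed, cfg, index=False)
        corr = phenostats.pearson_correlations(means["across"])
        io.write_table(corr, outdir / "correlations.tsv", seed, cfg)
        for t in traits:
            aov = phenostats.anova(phenotypes, t, "across")
            io.write_table(aov, outdir / f"anova_{t}.tsv", seed, cfg)
        for key, df in means.items():
            io.write_table(df, outdir / f"line_means_{key}.tsv", seed, cfg)
    except Exception as exc:  # noqa: BLE001
        _fail("phenostats", exc)

    # --- relatedness ------------------------------------------------------
    try:
        _stage("relatedness")
        if parent_raw is not None:
            parents = parent_raw[informative.columns]
        else:
            scheme_cfg = (config.simulate or {}).get("scheme", {})
            scheme = simpop.CrossingScheme(**scheme_cfg)
            parents = relatedness.parent_profiles(
                informative.columns,
                recurrent_labels=tuple(dict(scheme.recurrent_labels).values()),
                donor_label=scheme.donor_label,
            )
        entities = pd.concat([raw_states.loc[informative.index, informative.columns], parents])
        gs = relatedness.simple_matching(entities)
        coords, evr = relatedness.pc_embedding(gs)
        io.write_table(gs, outdir / "gs_matrix.tsv", seed, cfg)
        coords["explained_variance_PC1"] = evr[0]
        coords["explained_variance_PC2"] = evr[1] if len(evr) > 1 else np.nan
        io.write_table(coords, outdir / "pc_coordinates.tsv", seed, cfg)
        log.append(f"PC1/PC2 explained variance: {evr[0]:.3f}/{evr[1]:.3f}")
    except Exception as exc:  # noqa: BLE001
        _fail("relatedness", exc)

    # --- gwas -------------------------------------------------------------
    try:
        _stage("gwas")
        gw = config.gwas
        mta, scan = gwas.run_all_models(
            means,
            imputed,
            families,
            gmap,
            traits=gw.get("traits") or traits + ratio_traits,
            ratio_traits=ratio_traits,
            alpha=float(gw.get("alpha", 0.05)),
            window_cm=float(gw.get("window_cm", 1.0)),
            criterion=gw.get("criterion", "bic"),
            return_scans=True,
        )
        io.write_table(mta, outdir / "mta.tsv", seed, cfg, index=False)
        io.write_table(scan, outdir / "scan.tsv", seed, cfg, index=False)
        log.append(f"{len(mta)} MTAs across {scan.groupby(['trait', 'model', 'family_scope', 'n_scope']).ngroups} model applications")
    except Exception as exc:  # noqa: BLE001
        _fail("gwas", exc)

    # --- summarize --------------------------------------------------------
    try:
        _stage("summarize")
        qtls = qtlsum.merge_mtas(mta, gmap, window_cm=float(config.qtl.get("window_cm", 5.0)))
        cross, qtl_table = qtlsum.summary_tables(qtls, mta)
        io.write_table(qtl_table, outdir / "qtl.tsv", seed, cfg, index=False)
        io.write_table(cross, outdir / "mta_crosstab.tsv", seed, cfg)
        log.append(f"{len(qtls)} QTL after 5-cM merging")
    except Exception as exc:  # noqa: BLE001
        _fail("summarize", exc)

    manifest = {
        "tool": "abqtl",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": io.config_hash(cfg),
        "n_lines": int(genotypes.shape[0]),
        "n_snps_scored": int(genotypes.shape[1]),
        "n_snps_informative": int(informative.shape[1]),
        "n_mtas": int(len(mta)),
        "n_qtl": int(len(qtls)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir


def _ratio_vc(phenotypes, means, ratio_trait, lo, hi):
    """Variance components of a ratio trait from its per-environment ratios.

    The ratio is defined between N levels, so the within-N model Y = G + E + eps
    is fitted on per-environment N0/N1 ratios of the underlying trait.
    """
    base = ratio_trait[: -len("_ratio")]
    sub = phenotypes[phenotypes["trait"] == base]
    wide = sub.pivot_table(index=["line_id", "environment"], columns="n_level", values="value")
    if lo not in wide.columns or hi not in wide.columns:
        raise ValueError(f"ratio trait {ratio_trait!r} needs both N levels")
    ratio = (wide[lo] / wide[hi]).rename("value").reset_index()
    ratio["n_level"] = "across"
    ratio["trait"] = ratio_trait
    return phenostats.variance_components(ratio, ratio_trait, "within")
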