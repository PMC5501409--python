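"""Simulation of tri-parental advanced-backcross (BCₖFₗ) wheat populations.

The SW84-style design crosses one synthetic wild donor to two elite
recurrent parents, backcrosses twice, selfs three times, and genotypes the
resulting lines at mapped biallelic SNPs, scored as the dosage of the donor
("exotic") allele: 0 = homozygous elite, 1 = heterozygous, 2 = homozygous
donor.  This module generates such populations gamete by gamete -- meiosis
under the Haldane mapping function (no crossover interference), independent
assortment across chromosomes -- together with phenotypes following the
additive mixed model

    Y = mu + sum(dosage * a) + G + E + N + GxE + GxN + eps

where G is a polygenic line effect, E/N are fixed environment and nitrogen
effects and GxE/GxN/eps are Gaussian noise components.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WHEAT_CHROMOSOMES",
    "GeneticMap",
    "CrossingScheme",
    "PlantedQtl",
    "PhenoModelConfig",
    "SW84_SCHEME",
    "SimulatedPopulation",
    "expected_genotype_frequencies",
    "haldane",
    "uniform_map",
    "simulate_gamete",
    "simulate_population",
    "simulate_phenotypes",
]

#: The 21 chromosomes of hexaploid bread wheat (7 groups x A/B/D genomes).
WHEAT_CHROMOSOMES: tuple[str, ...] = tuple(
    f"{group}{genome}" for group in range(1, 8) for genome in "ABD"
)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered SNP loci with chromosome labels and positions in centiMorgan.

    Positions must be non-decreasing within each chromosome; SNP ids must be
    unique and every chromosome must carry at least one locus.
    """

    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        snp_ids = np.asarray(self.snp_ids, dtype=object)
        chroms = np.asarray(self.chromosomes, dtype=object)
        pos = np.asarray(self.positions, dtype=float)
        if not (len(snp_ids) == len(chroms) == len(pos)):
            raise ValueError("map columns have inconsistent lengths")
        if len(snp_ids) == 0:
            raise ValueError("empty genetic map")
        if len(set(snp_ids)) != len(snp_ids):
            raise ValueError("duplicate SNP ids in map")
        if np.any(pos < 0) or not np.all(np.isfinite(pos)):
            raise ValueError("cM positions must be finite and >= 0")
        for c in pd.unique(chroms):
            p = pos[chroms == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")
        object.__setattr__(self, "snp_ids", snp_ids)
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_loci(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": self.chromosomes,
                "position_cM": self.positions,
            }
        )

    def position_of(self, snp_id: str) -> tuple[str, float]:
        """Return (chromosome, cM position) of a SNP, raising KeyError if absent."""
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not on map")
        i = int(idx[0])
        return str(self.chromosomes[i]), float(self.positions[i])

    def chromosome_starts(self) -> np.ndarray:
        """Boolean mask: True where a locus opens a new chromosome."""
        start = np.ones(len(self), dtype=bool)
        start[1:] = self.chromosomes[1:] != self.chromosomes[:-1]
        return start


@dataclass(frozen=True)
class CrossingScheme:
    """A backcross-selfing pedigree: BCₖFₗ with k = n_backcrosses, l = n_selfings + 1."""

    n_backcrosses: int = 2
    n_selfings: int = 3
    family_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"D84": 154, "T84": 205}
    )
    n_bc1_plants: Mapping[str, int] = field(
        default_factory=lambda: {"D84": 27, "T84": 18}
    )
    donor_label: str = "Syn084L"
    recurrent_labels: Mapping[str, str] = field(
        default_factory=lambda: {"D84": "Devon", "T84": "Triso"}
    )

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0 or self.n_selfings < 0:
            raise ValueError("generation counts must be >= 0")
        for fam, n in self.family_sizes.items():
            if n <= 0:
                raise ValueError(f"family {fam!r} has non-positive size {n}")


#: The SW84 preset: two backcrosses, three selfings, families of 154 and 205 lines.
SW84_SCHEME = CrossingScheme()


@dataclass(frozen=True)
class PlantedQtl:
    """A known additive QTL placed at a mapped SNP for simulation.

    ``additive_effect`` is in trait units per donor-allele substitution, so the
    homozygous-donor minus homozygous-elite contrast (the "exotic effect")
    equals ``2 * additive_effect``.  ``families`` / ``n_levels`` restrict where
    the effect is active (None = everywhere).
    """

    snp_id: str
    trait: str
    additive_effect: float
    families: frozenset[str] | None = None
    n_levels: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.additive_effect):
            raise ValueError("additive effect must be finite")


@dataclass(frozen=True)
class PhenoModelConfig:
    """Variance structure and design effects for phenotype simulation.

    Defaults follow the generic simulation conditions used throughout the
    package's validation: V_G = 2, V_GxE = 1, V_GxN = 1, V_R = 2 on a design
    of three environments and two nitrogen levels.
    """

    trait_means: Mapping[str, float] = field(default_factory=lambda: {"trait": 0.0})
    environment_effects: Mapping[str, float] = field(
        default_factory=lambda: {"D04": 0.0, "H04": 0.4, "H05": -0.4}
    )
    n_level_effects: Mapping[str, float] = field(
        default_factory=lambda: {"N0": -1.0, "N1": 1.0}
    )
    v_g: float = 2.0
    v_gxe: float = 1.0
    v_gxn: float = 1.0
    v_r: float = 2.0

    def __post_init__(self) -> None:
        for name in ("v_g", "v_gxe", "v_gxn", "v_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be >= 0")


def expected_genotype_frequencies(
    scheme: CrossingScheme | None = None,
    *,
    n_backcrosses: int | None = None,
    n_selfings: int | None = None,
) -> tuple[float, float, float]:
    """Expected single-locus genotype-class frequencies after the crossing scheme.

    Returns ``(f_homo_elite, f_het, f_homo_exotic)`` from the per-generation
    recursion: the F1 is fully heterozygous; each backcross to the recurrent
    parent halves heterozygosity, moving it into the homozygous-elite class
    (a homozygous-donor plant backcrossed yields heterozygotes); each selfing
    halves heterozygosity, splitting the loss equally between the two
    homozygous classes.

    >>> expected_genotype_frequencies(n_backcrosses=2, n_selfings=3)
    (0.859375, 0.03125, 0.109375)
    """
    if scheme is not None:
        nb, ns = scheme.n_backcrosses, scheme.n_selfings
    else:
        nb = 2 if n_backcrosses is None else n_backcrosses
        ns = 3 if n_selfings is None else n_selfings
    if nb < 0 or ns < 0:
        raise ValueError("generation counts must be >= 0")
    f0, h, f2 = 0.0, 1.0, 0.0  # F1
    for _ in range(nb):
        f0, h, f2 = f0 + h / 2.0, h / 2.0 + f2, 0.0
    for _ in range(ns):
        f0, h, f2 = f0 + h / 4.0, h / 2.0, f2 + h / 4.0
    return f0, h, f2


def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM.

    r = (1 - exp(-2 d / 100)) / 2; no crossover interference assumed.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def uniform_map(
    n_snps: int = 4096,
    chromosomes: Sequence[str] = WHEAT_CHROMOSOMES,
    chromosome_length_cM: float = 160.0,
) -> GeneticMap:
    """Evenly spaced map: loci spread uniformly over equally long chromosomes.

    ``n_snps`` loci are split as evenly as possible across the chromosomes
    (earlier chromosomes take the remainder), giving ~0.8 cM spacing for the
    default 4,096 loci on 21 x 160 cM, close to the density of a 90k-array
    consensus map after informativeness filtering.
    """
    if n_snps < len(chromosomes):
        raise ValueError("need at least one SNP per chromosome")
    base, extra = divmod(n_snps, len(chromosomes))
    ids, chroms, pos = [], [], []
    for i, c in enumerate(chromosomes):
        k = base + (1 if i < extra else 0)
        p = np.linspace(0.0, chromosome_length_cM, k)
        for j in range(k):
            ids.append(f"snp_{c}_{j:04d}")
            chroms.append(c)
            pos.append(p[j])
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(pos))


# ---------------------------------------------------------------------------
# Meiosis


def _switch_probabilities(gmap: GeneticMap) -> np.ndarray:
    """Per-locus probability that the gamete switches parental haplotype.

    The first locus of each chromosome gets 0.5 (a fresh random choice =
    independent assortment); subsequent loci get the Haldane recombination
    fraction for the gap to their predecessor.
    """
    r = np.empty(len(gmap))
    gaps = np.diff(gmap.positions)
    r[1:] = haldane(gaps)
    r[gmap.chromosome_starts()] = 0.5
    return r


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, switch_p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised meiosis: one gamete per row of the (m, L) haplotype pairs."""
    if hap_a.shape != hap_b.shape or hap_a.shape[-1] != len(switch_p):
        raise ValueError("haplotype shape does not match the map")
    switches = (rng.random(hap_a.shape) < switch_p).astype(np.uint8)
    # cumulative XOR along loci: which parental haplotype is currently copied
    state = np.bitwise_xor.accumulate(switches, axis=-1)
    return np.where(state & 1, hap_b, hap_a).astype(np.int8)


def simulate_gamete(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one recombinant gamete from a pair of parental haplotypes.

    Crossovers follow the Haldane mapping function between adjacent mapped
    loci; chromosomes assort independently.
    """
    hap_a = np.atleast_2d(np.asarray(parent_haplotypes[0], dtype=np.int8))
    hap_b = np.atleast_2d(np.asarray(parent_haplotypes[1], dtype=np.int8))
    return _gametes(hap_a, hap_b, _switch_probabilities(gmap), rng)[0]


@dataclass
class SimulatedPopulation:
    """Full output of a population simulation.

    ``genotypes`` holds exotic dosages (donor-allele counts, the coding every
    analysis stage uses); ``raw_alleles`` holds array-style B-allele dosages,
    which differ from exotic dosages at "divergent" SNPs — loci where the two
    recurrent parents carry different array alleles and the donor is
    heterozygous, so each family's F1 fixes one donor allele.  Raw states are
    what an array reports and what similarity analyses see; at divergent loci
    they make the families distinguishable, as in real multi-parent panels.
    """

    genotypes: pd.DataFrame
    families: pd.Series
    raw_alleles: pd.DataFrame
    parent_raw: pd.DataFrame
    pedigree: pd.DataFrame
    divergent: pd.Series


def simulate_population(
    scheme: CrossingScheme,
    gmap: GeneticMap,
    rng: np.random.Generator | int | None = None,
    *,
    missing_rate: float = 0.0,
    divergent_fraction: float = 0.0,
    return_pedigree: bool = False,
    full: bool = False,
) -> (
    tuple[pd.DataFrame, pd.Series]
    | tuple[pd.DataFrame, pd.Series, pd.DataFrame]
    | SimulatedPopulation
):
    """Simulate the full pedigree of a backcross-selfing population.

    For each family, one F1 (donor x recurrent) is backcrossed
    ``n_backcrosses`` times -- the first backcross generation is a configurable
    number of distinct BC1 plants, under which the lines nest -- and each line
    then descends through ``n_selfings`` generations of single-seed selfing.

    Returns ``(genotypes, families)`` where ``genotypes`` is a line x SNP
    DataFrame of exotic dosages (0/1/2; NaN where masked missing) and
    ``families`` maps line id -> family label.  With ``return_pedigree`` a
    third DataFrame records each line's BC1-plant ancestor.  With ``full``
    a :class:`SimulatedPopulation` is returned, including raw allele states
    under ``divergent_fraction`` recurrent-parent divergence.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if not 0.0 <= divergent_fraction <= 1.0:
        raise ValueError("divergent_fraction must be in [0, 1]")
    L = len(gmap)
    switch_p = _switch_probabilities(gmap)
    zeros = np.zeros(L, dtype=np.int8)
    ones = np.ones(L, dtype=np.int8)
    divergent = (
        rng.random(L) < divergent_fraction
        if divergent_fraction > 0
        else np.zeros(L, dtype=bool)
    )

    all_dosage, all_raw, line_ids, fam_labels, bc1_ids = [], [], [], [], []
    parent_raw_rows = {}
    for fam_idx, (fam, n_lines) in enumerate(scheme.family_sizes.items()):
        # F1: one donor haplotype, one recurrent haplotype at every locus.
        hap_a = np.tile(ones, (1, 1))
        hap_b = np.tile(zeros, (1, 1))
        n_founders = dict(scheme.n_bc1_plants).get(fam, n_lines)
        for gen in range(scheme.n_backcrosses):
            if gen == 0:
                # distinct BC1 plants; lines are assigned to them below
                m = max(1, min(n_founders, n_lines))
                idx = np.zeros(m, dtype=int)
            else:
                # one BCk plant per line, each from its line's BC1 ancestor
                if gen == 1:
                    assign = rng.integers(0, hap_a.shape[0], size=n_lines)
                    bc1_of_line = assign
                else:
                    assign = np.arange(n_lines)
                idx = assign
            gam = _gametes(hap_a[idx], hap_b[idx], switch_p, rng)
            hap_a, hap_b = gam, np.tile(zeros, (len(idx), 1))
        if scheme.n_backcrosses == 0:
            hap_a = np.tile(ones, (n_lines, 1))
            hap_b = np.tile(zeros, (n_lines, 1))
            bc1_of_line = np.full(n_lines, -1)
        elif scheme.n_backcrosses == 1:
            assign = rng.integers(0, hap_a.shape[0], size=n_lines)
            bc1_of_line = assign
            hap_a, hap_b = hap_a[assign], hap_b[assign]
        for _ in range(scheme.n_selfings):
            hap_a, hap_b = (
                _gametes(hap_a, hap_b, switch_p, rng),
                _gametes(hap_a, hap_b, switch_p, rng),
            )
        dosage = (hap_a + hap_b).astype(np.int8)
        all_dosage.append(dosage)
        # raw array states: B-allele counts.  The family's F1 fixes one donor
        # allele at each divergent locus; the recurrent allele alternates
        # between families there (non-divergent loci: recurrent A, donor B).
        donor_allele = np.where(divergent, rng.integers(0, 2, size=L), 1).astype(np.int8)
        rec_allele = np.where(divergent, fam_idx % 2, 0).astype(np.int8)
        all_raw.append(dosage * donor_allele + (2 - dosage) * rec_allele)
        rec_label = dict(scheme.recurrent_labels).get(fam, f"recurrent_{fam}")
        parent_raw_rows[rec_label] = (2 * rec_allele).astype(float)
        line_ids.extend(f"{fam}_{i + 1:03d}" for i in range(n_lines))
        fam_labels.extend([fam] * n_lines)
        bc1_ids.extend(
            f"{fam}_BC1_{int(b) + 1:02d}" if b >= 0 else "F1" for b in bc1_of_line
        )
    parent_raw_rows[scheme.donor_label] = np.where(divergent, 1.0, 2.0)

    dosages = np.concatenate(all_dosage, axis=0).astype(float)
    raw = np.concatenate(all_raw, axis=0).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
        raw[mask] = np.nan
    index = pd.Index(line_ids, name="line_id")
    genotypes = pd.DataFrame(dosages, index=index, columns=gmap.snp_ids)
    families = pd.Series(fam_labels, index=index, name="family")
    pedigree = pd.DataFrame({"bc1_plant": bc1_ids}, index=index)
    if full:
        return SimulatedPopulation(
            genotypes=genotypes,
            families=families,
            raw_alleles=pd.DataFrame(raw, index=index, columns=gmap.snp_ids),
            parent_raw=pd.DataFrame(parent_raw_rows, index=gmap.snp_ids).T,
            pedigree=pedigree,
            divergent=pd.Series(divergent, index=gmap.snp_ids, name="divergent"),
        )
    if return_pedigree:
        return genotypes, families, pedigree
    return genotypes, families


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    planted_qtl: Sequence[PlantedQtl],
    config: PhenoModelConfig,
    rng: np.random.Generator | int | None = None,
    *,
    families: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate trait records for every line x environment x N-level cell.

    Each record's value is the trait mean, plus planted-QTL contributions
    (dosage x additive effect, restricted to the QTL's active families and N
    levels), plus a polygenic line effect ~ N(0, V_G), fixed environment and
    N effects, interaction draws ~ N(0, V_GxE) and N(0, V_GxN), and residual
    ~ N(0, V_R).  Fully reproducible given the seed.

    Returns a long-format DataFrame (line_id, environment, n_level, trait, value).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for q in planted_qtl:
        if q.snp_id not in genotypes.columns:
            raise KeyError(f"planted QTL at {q.snp_id!r} absent from genotypes")
        if q.trait not in config.trait_means:
            raise KeyError(f"planted QTL trait {q.trait!r} has no trait mean")
    lines = genotypes.index.to_numpy()
    envs = list(config.environment_effects)
    nlevs = list(config.n_level_effects)
    g, e, n = len(lines), len(envs), len(nlevs)

    records = []
    for trait, mu in config.trait_means.items():
        base = np.zeros((g, e, n))
        for q in planted_qtl:
            if q.trait != trait:
                continue
            dos = genotypes[q.snp_id].to_numpy(dtype=float)
            dos = np.nan_to_num(dos, nan=float(np.nanmean(dos)))
            contrib = dos[:, None, None] * q.additive_effect
            active = np.ones((g, e, n), dtype=float)
            if q.families is not None:
                if families is None:
                    raise ValueError("QTL restricted by family but no families given")
                active *= families.loc[lines].isin(q.families).to_numpy(dtype=float)[:, None, None]
            if q.n_levels is not None:
                active *= np.array([lv in q.n_levels for lv in nlevs], dtype=float)[None, None, :]
            base += contrib * active
        line_eff = rng.normal(0.0, np.sqrt(config.v_g), size=g)
        gxe = rng.normal(0.0, np.sqrt(config.v_gxe), size=(g, e))
        gxn = rng.normal(0.0, np.sqrt(config.v_gxn), size=(g, n))
        resid = rng.normal(0.0, np.sqrt(config.v_r), size=(g, e, n))
        env_eff = np.array([config.environment_effects[v] for v in envs])
        n_eff = np.array([config.n_level_effects[v] for v in nlevs])
        y = (
            mu
            + base
            + line_eff[:, None, None]
            + env_eff[None, :, None]
            + n_eff[None, None, :]
            + gxe[:, :, None]
            + gxn[:, None, :]
            + resid
        )
        for j, env in enumerate(envs):
            for k, nl in enumerate(nlevs):
                records.append(
                    pd.DataFrame(
                        {
                            "line_id": lines,
                            "environment": env,
                            "n_level": nl,
                            "trait": trait,
                            "value": y[:, j, k],
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)
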