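"""Marker quality control for backcross-derived SNP dosage matrices.

Filters follow the order used for array-genotyped advanced-backcross
populations: drop failed assays, keep markers polymorphic in both families,
discard markers whose genotype-class counts deviate from the crossing-scheme
expectation (segregation distortion, Pearson chi-square), keep markers with
a map position, and finally mean-impute the remaining missing calls so that
multiple-regression association models can be fitted on a complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationTestResult",
    "filter_failure_rate",
    "classify_polymorphism",
    "segregation_test",
    "segregation_test_matrix",
    "informative_set",
    "mni_impute",
    "exotic_genome_proportion",
]


@dataclass(frozen=True)
class SegregationTestResult:
    """Chi-square goodness-of-fit of observed genotype counts to expectation."""

    snp_id: str
    n0: int
    n1: int
    n2: int
    chi_square: float
    p_value: float
    distorted: bool


def filter_failure_rate(genotypes: pd.DataFrame, max_missing_fraction: float = 1.0) -> pd.DataFrame:
    """Drop SNP columns whose missing-call fraction exceeds the threshold.

    The default 1.0 removes only completely failed assays (failure rate of
    100%); 0.0 keeps only complete columns.  Column order is preserved.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = genotypes.isna().mean(axis=0)
    keep = frac.to_numpy() <= max_missing_fraction
    if max_missing_fraction >= 1.0:
        keep = frac.to_numpy() < 1.0
    return genotypes.loc[:, keep]


def classify_polymorphism(genotypes: pd.DataFrame, families: pd.Series) -> pd.Series:
    """Classify each SNP as monomorphic / polymorphic-in-one-family / polymorphic-in-both.

    A SNP is polymorphic within a family iff at least two distinct non-missing
    scores occur among that family's lines.  When raw array states are
    available (they differ from exotic dosages at loci where the recurrent
    parents diverge), pass those: the array observes raw states, and a locus
    whose donor and recurrent alleles coincide within a family is monomorphic
    there even though donor descent varies.
    """
    fams = pd.unique(families.loc[genotypes.index])
    if len(fams) < 2:
        raise ValueError("need at least two families")
    poly_count = np.zeros(genotypes.shape[1], dtype=int)
    for fam in fams:
        sub = genotypes.loc[families.loc[genotypes.index] == fam]
        if len(sub) == 0:
            raise ValueError(f"family {fam!r} has no lines")
        poly_count += (sub.nunique(axis=0, dropna=True) >= 2).to_numpy().astype(int)
    labels = np.where(
        poly_count == 0,
        "monomorphic",
        np.where(poly_count < len(fams), "polymorphic-in-one-family", "polymorphic-in-both"),
    )
    return pd.Series(labels, index=genotypes.columns, name="polymorphism")


def segregation_test(
    counts: tuple[int, int, int],
    expected_probs: tuple[float, float, float],
    alpha: float = 0.05,
    snp_id: str = "",
) -> SegregationTestResult:
    """Pearson chi-square test of genotype counts against expected class probabilities.

    Three classes fully specified by the crossing scheme give 2 degrees of
    freedom.  A class with zero expected probability but non-zero observed
    count yields an infinite statistic (p = 0, distorted).
    """
    obs = np.asarray(counts, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != (3,) or np.any(obs < 0):
        raise ValueError("counts must be three non-negative numbers")
    total = obs.sum()
    if total == 0:
        raise ValueError("no non-missing calls")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1")
    exp = total * probs
    if np.any((exp == 0) & (obs > 0)):
        chi2, p = np.inf, 0.0
    else:
        nz = exp > 0
        chi2 = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
        p = float(stats.chi2.sf(chi2, df=2))
    return SegregationTestResult(
        snp_id, int(obs[0]), int(obs[1]), int(obs[2]), chi2, p, bool(p < alpha)
    )


def segregation_test_matrix(
    genotypes: pd.DataFrame,
    expected_probs: tuple[float, float, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the segregation test to every SNP column (family-pooled counts).

    Returns a per-SNP DataFrame with observed counts, chi-square, p-value and
    the distortion flag.
    """
    arr = genotypes.to_numpy(dtype=float)
    n0 = np.nansum(arr == 0, axis=0)
    n1 = np.nansum(arr == 1, axis=0)
    n2 = np.nansum(arr == 2, axis=0)
    total = n0 + n1 + n2
    probs = np.asarray(expected_probs, dtype=float)
    exp = total[:, None] * probs[None, :]
    obs = np.stack([n0, n1, n2], axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
    chi2 = terms.sum(axis=1)
    chi2 = np.where(((exp == 0) & (obs > 0)).any(axis=1), np.inf, chi2)
    pvals = stats.chi2.sf(chi2, df=2)
    pvals = np.where(total == 0, np.nan, pvals)
    return pd.DataFrame(
        {
            "n0": n0.astype(int),
            "n1": n1.astype(int),
            "n2": n2.astype(int),
            "chi_square": chi2,
            "p_value": pvals,
            "distorted": pvals < alpha,
        },
        index=genotypes.columns,
    )


def informative_set(
    genotypes: pd.DataFrame,
    families: pd.Series,
    gmap,
    test_results: pd.DataFrame | None = None,
    expected_probs: tuple[float, float, float] | None = None,
    alpha: float = 0.05,
    states: pd.DataFrame | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Select informative SNPs: polymorphic in both families, well-segregating, mapped.

    ``test_results`` may be precomputed (from :func:`segregation_test_matrix`);
    otherwise ``expected_probs`` must be given and tests are run here.
    ``states`` optionally supplies the raw array states used for the
    polymorphism classification (defaults to the dosage matrix itself).
    Counts surviving each filter stage are appended to ``log`` when provided.
    """
    stages = [("scored", genotypes.shape[1])]
    poly = classify_polymorphism(genotypes if states is None else states, families)
    keep = poly == "polymorphic-in-both"
    stages.append(("polymorphic-in-both-families", int(keep.sum())))
    if test_results is None:
        if expected_probs is None:
            raise ValueError("need test_results or expected_probs")
        test_results = segregation_test_matrix(genotypes, expected_probs, alpha)
    distorted = test_results["distorted"].reindex(genotypes.columns).fillna(False)
    keep &= ~distorted
    stages.append(("non-distorted", int(keep.sum())))
    mapped = genotypes.columns.isin(gmap.snp_ids)
    keep &= pd.Series(mapped, index=genotypes.columns)
    stages.append(("mapped", int(keep.sum())))
    if log is not None:
        log.extend(f"{name}: {n}" for name, n in stages)
    return genotypes.loc[:, keep.to_numpy()]


def mni_impute(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean imputation (MNI): replace missing calls with the SNP's mean dosage.

    Observed values are untouched; the output is real-valued.  Raises on an
    all-missing column, which should have been removed by the failure filter.
    """
    if genotypes.isna().all(axis=0).any():
        bad = genotypes.columns[genotypes.isna().all(axis=0)][0]
        raise ValueError(f"SNP {bad!r} has no observed calls")
    return genotypes.fillna(genotypes.mean(axis=0))


def exotic_genome_proportion(genotypes: pd.DataFrame) -> pd.Series:
    """Per-line proportion of the genome covered by donor (exotic) alleles.

    Mean of dosage/2 over each line's non-missing SNPs.
    """
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    if genotypes.isna().all(axis=1).any():
        bad = genotypes.index[genotypes.isna().all(axis=1)][0]
        raise ValueError(f"line {bad!r} has no observed calls")
    return (genotypes / 2.0).mean(axis=1).rename("exotic_proportion")
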