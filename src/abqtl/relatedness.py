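"""Simple-matching genetic similarity and its principal-component embedding.

Similarity between two entities (lines or parents) is the fraction of
pairwise non-missing SNPs at which they carry the identical genotype state
(0, 1 or 2).  Parents enter as dosage profiles: a recurrent parent is 0 at
every informative SNP, the donor 2.  A PCA of the similarity matrix —
treating each entity's similarity vector as its feature vector — separates
the families of a tri-parental population and places the shared donor
between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["parent_profiles", "simple_matching", "pc_embedding"]


def parent_profiles(
    snp_ids,
    recurrent_labels=("Devon", "Triso"),
    donor_label: str = "Syn084L",
) -> pd.DataFrame:
    """Dosage profiles of the founder parents at the informative SNPs.

    Recurrent (elite) parents are homozygous dosage 0 everywhere; the donor is
    homozygous dosage 2 (informative SNPs are by construction polymorphic
    between donor and both recurrent parents).
    """
    rows = {lab: np.zeros(len(snp_ids)) for lab in recurrent_labels}
    rows[donor_label] = np.full(len(snp_ids), 2.0)
    return pd.DataFrame(rows, index=snp_ids).T


def simple_matching(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise simple-matching similarity over the three genotype states.

    GS(i, j) = (# SNPs with identical state among pairwise non-missing calls)
    / (# pairwise non-missing calls).  Rows are entities (lines and parents);
    values must be in {0, 1, 2, NaN}.  A pair with no shared non-missing SNP
    raises.
    """
    arr = genotypes.to_numpy(dtype=float)
    obs = ~np.isnan(arr)
    valid = obs.astype(float) @ obs.astype(float).T
    if np.any(valid == 0):
        raise ValueError("entity pair with no shared non-missing SNPs")
    matches = np.zeros_like(valid)
    for state in (0.0, 1.0, 2.0):
        ind = ((arr == state) & obs).astype(float)
        matches += ind @ ind.T
    gs = matches / valid
    np.fill_diagonal(gs, 1.0)
    return pd.DataFrame(gs, index=genotypes.index, columns=genotypes.index)


def pc_embedding(
    gs: pd.DataFrame, n_components: int = 2, method: str = "pca"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component embedding of a similarity matrix.

    ``method='pca'`` (default) treats each entity's row of the similarity
    matrix as its feature vector and performs covariance PCA: columns are
    centered and the eigenvectors of the resulting covariance matrix give the
    coordinates.  ``method='pcoa'`` performs classical multidimensional
    scaling on the dissimilarity 1 - GS (double-centered Gower matrix).

    Returns (coordinates DataFrame indexed like ``gs``, explained-variance
    fractions, non-increasing, summing to <= 1).
    """
    mat = gs.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    n = mat.shape[0]
    if method == "pca":
        centered = mat - mat.mean(axis=0, keepdims=True)
        cov = centered.T @ centered / max(n - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        coords = centered @ evecs[:, :n_components]
    elif method == "pcoa":
        d2 = (1.0 - mat) ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        evals, evecs = np.linalg.eigh(b)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
        coords = evecs[:, :n_components] * np.sqrt(evals[:n_components])[None, :]
    else:
        raise ValueError(f"unknown method {method!r}")
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=gs.index, columns=cols), frac[: min(n, len(frac))]
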