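"""Four-model marker-trait association scan with cofactor-corrected regression.

Association testing follows the two-step scheme used for multi-family
advanced-backcross populations: per trait and scope, background SNP
cofactors are first chosen by greedy forward selection under an information
criterion; each mapped SNP is then tested in the fixed-effects multiple
regression

    Y = mu + SNP + Fam + SNPxFam + Cofactors(> 1 cM) + eps

where Y is the adjusted line mean, SNP the exotic-allele dosage (0/1/2)
treated as a quantitative covariate, Fam the family main effect and SNPxFam
its interaction with dosage (both dropped in within-family scans), and only
cofactors farther than 1 cM from the tested SNP enter the model.  Raw
slope p-values are adjusted by the Holm step-down Bonferroni procedure
within each trait x model application; SNPs with adjusted p < 0.05 are
declared marker-trait associations (MTAs).  The "exotic effect" — the
phenotypic consequence of substituting both elite alleles by donor alleles —
is twice the fitted slope.

The four model scopes: 1 = across families, across N levels; 2 = within one
family, across N; 3 = across families, within one N level; 4 = within one
family, within one N level.  Nine applications per regular trait, three
(models 1 and 2 at across-N) per N-ratio trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "select_cofactors",
    "snp_scan",
    "holm_adjust",
    "declare_mtas",
    "run_all_models",
    "model_applications",
]

ACROSS = "across"


@dataclass(frozen=True)
class ModelSpec:
    """One of the four association-model scopes (family x N level)."""

    model_id: int
    family_scope: str = ACROSS  # "across" or a family label
    n_scope: str = ACROSS  # "across" or an N-level label

    def __post_init__(self) -> None:
        expected = {
            1: (True, True),
            2: (False, True),
            3: (True, False),
            4: (False, False),
        }
        if self.model_id not in expected:
            raise ValueError("model_id must be 1-4")
        fam_across, n_across = expected[self.model_id]
        if (self.family_scope == ACROSS) != fam_across or (self.n_scope == ACROSS) != n_across:
            raise ValueError(
                f"scope ({self.family_scope}, {self.n_scope}) inconsistent with model {self.model_id}"
            )


def model_applications(
    families: list[str], n_levels: list[str], ratio: bool = False
) -> list[ModelSpec]:
    """Enumerate the model applications for one trait.

    Regular traits get nine applications (1; 2 per family; 3 per N level;
    4 per family x N level); ratio traits, defined across N levels only, get
    three (1; 2 per family).
    """
    specs = [ModelSpec(1)]
    specs += [ModelSpec(2, family_scope=f) for f in families]
    if not ratio:
        specs += [ModelSpec(3, n_scope=nl) for nl in n_levels]
        specs += [
            ModelSpec(4, family_scope=f, n_scope=nl)
            for f in families
            for nl in n_levels
        ]
    return specs


def select_cofactors(
    dosages: pd.DataFrame,
    y: pd.Series,
    criterion: str = "bic",
    max_steps: int | None = None,
) -> list[str]:
    """Greedy forward selection of background SNPs for a trait.

    SNP columns (complete, imputed dosages) enter a linear model for ``y``
    one at a time, each step adding the SNP with the largest residual-sum-of-
    squares reduction; selection stops when the information criterion no
    longer improves.  The default ``"bic"`` is the extended (high-dimensional)
    Schwarz criterion with per-parameter penalty log n + 2 log p: because each
    step picks the best of p candidate markers, the classical log n penalty
    alone is beaten by the expected maximal chi-square of ~2 log p even under
    a pure-noise trait, and the extension restores near-empty null selections.
    ``"aic"`` gives the classical Akaike penalty.  Collinear or constant
    candidates are never selected, so duplicated columns contribute at most
    once.  Returns selected SNP ids in selection order.
    """
    common = dosages.index.intersection(y.dropna().index)
    X = dosages.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 lines for cofactor selection")
    penalty = {"bic": np.log(n) + 2.0 * np.log(max(p, 2)), "aic": 2.0}[criterion]
    if max_steps is None:
        max_steps = max(1, min(p, n // 4))
    Xr = X - X.mean(axis=0, keepdims=True)
    r = yv - yv.mean()
    rss = float(r @ r)
    if rss == 0.0:
        return []
    best_ic = n * np.log(rss / n) + penalty  # intercept-only
    selected: list[int] = []
    norms_tol = 1e-10 * max(1.0, float(np.max(np.sum(Xr**2, axis=0))))
    for _ in range(max_steps):
        denom = np.sum(Xr**2, axis=0)
        usable = denom > norms_tol
        if not usable.any():
            break
        score = np.zeros(p)
        score[usable] = (Xr[:, usable].T @ r) ** 2 / denom[usable]
        j = int(np.argmax(score))
        new_rss = rss - float(score[j])
        if new_rss <= 0:
            new_rss = np.finfo(float).tiny
        ic = n * np.log(new_rss / n) + penalty * (len(selected) + 2)
        if ic >= best_ic:
            break
        best_ic, rss = ic, new_rss
        q = Xr[:, j] / np.sqrt(denom[j])
        Xr -= np.outer(q, q @ Xr)
        r = r - q * float(q @ r)
        selected.append(j)
    return [str(dosages.columns[j]) for j in selected]


def _ols(X: np.ndarray, y: np.ndarray, need_cov: bool = False):
    """Minimum-norm least squares via one SVD.

    Returns (beta, SSE, rank[, pinv]) where ``pinv`` (on request) is the
    Moore-Penrose pseudo-inverse used for the slope's sampling variance:
    Var(beta) = sigma^2 * pinv @ pinv.T.
    """
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    nz = s > tol
    rank = int(nz.sum())
    s_inv = np.where(nz, 1.0 / np.where(nz, s, 1.0), 0.0)
    pinv = (vt.T * s_inv) @ u.T
    beta = pinv @ y
    resid = y - X @ beta
    sse = float(resid @ resid)
    if need_cov:
        return beta, sse, rank, pinv
    return beta, sse, rank


def snp_scan(
    y: pd.Series,
    dosages: pd.DataFrame,
    families: pd.Series,
    gmap,
    cofactors: list[str],
    spec: ModelSpec,
    window_cm: float = 1.0,
) -> pd.DataFrame:
    """Per-SNP multiple regression of line means on exotic dosage.

    ``y`` and ``dosages`` must already be restricted to the lines of the
    model's scope.  Family main and SNPxFam interaction terms are included
    only for across-family scopes with >= 2 families present.  Cofactor SNPs
    within ``window_cm`` of the tested SNP on the same chromosome — always
    including the tested SNP itself — are excluded from that SNP's model.

    Returns a DataFrame indexed by snp_id with columns chromosome,
    position_cM, slope, p_raw and r2_adj (incremental adjusted variance
    explained by the SNP term); SNPs monomorphic in scope get NaN rows.
    """
    common = dosages.index.intersection(y.dropna().index)
    X = dosages.loc[common]
    yv = y.loc[common].to_numpy(dtype=float)
    n = len(common)
    fam = families.loc[common]
    fam_levels = list(pd.unique(fam))
    use_family = spec.family_scope == ACROSS and len(fam_levels) >= 2
    fam_dummies = (
        np.stack([(fam == f).to_numpy(dtype=float) for f in fam_levels[1:]], axis=1)
        if use_family
        else np.empty((n, 0))
    )
    chrom = pd.Series(gmap.chromosomes, index=gmap.snp_ids)
    pos = pd.Series(gmap.positions, index=gmap.snp_ids)
    missing_map = [s for s in dosages.columns if s not in pos.index]
    if missing_map:
        raise KeyError(f"SNP {missing_map[0]!r} not on map")
    snp_chrom = chrom.reindex(dosages.columns).to_numpy()
    snp_pos = pos.reindex(dosages.columns).to_numpy(dtype=float)
    X_arr = X.to_numpy(dtype=float)
    cof_mat = X[cofactors].to_numpy(dtype=float) if cofactors else np.empty((n, 0))
    cof_chrom = chrom.reindex(cofactors).to_numpy()
    cof_pos = pos.reindex(cofactors).to_numpy(dtype=float)
    ss_total = float(np.sum((yv - yv.mean()) ** 2))
    intercept = np.ones((n, 1))
    base_all = np.concatenate([intercept, fam_dummies, cof_mat], axis=1)
    _, sse_red_all, _ = _ols(base_all, yv)

    rows = []
    for j, snp in enumerate(dosages.columns):
        d = X_arr[:, j]
        if np.ptp(d) == 0:
            rows.append((snp, snp_chrom[j], snp_pos[j], np.nan, np.nan, np.nan))
            continue
        near = (cof_chrom == snp_chrom[j]) & (np.abs(cof_pos - snp_pos[j]) <= window_cm)
        keep_cof = cof_mat[:, ~near]
        snp_cols = [d[:, None]]
        if use_family:
            snp_cols.append(d[:, None] * fam_dummies)
        snp_block = np.concatenate(snp_cols, axis=1)
        full = np.concatenate([intercept, snp_block, fam_dummies, keep_cof], axis=1)
        beta, sse_full, rank_full, pinv = _ols(full, yv, need_cov=True)
        if near.any():
            base = np.concatenate([intercept, fam_dummies, keep_cof], axis=1)
            _, sse_red, _ = _ols(base, yv)
        else:
            sse_red = sse_red_all
        df_resid = n - rank_full
        if df_resid <= 0 or sse_full <= 0:
            rows.append((snp, chrom[snp], pos[snp], float(beta[1]), 0.0, np.nan))
            continue
        sigma2 = sse_full / df_resid
        se = float(np.sqrt(sigma2 * float(pinv[1] @ pinv[1])))
        slope = float(beta[1])
        if se == 0.0:
            p_raw = 0.0 if slope != 0 else 1.0
        else:
            p_raw = float(2.0 * stats.t.sf(abs(slope) / se, df=df_resid))
        k = full.shape[1] - 1  # covariates, intercept excluded
        r2 = (sse_red - sse_full) / ss_total if ss_total > 0 else 0.0
        r2_adj = r2 - (1.0 - r2) * k / (n - k - 1) if n - k - 1 > 0 else np.nan
        rows.append((snp, chrom[snp], pos[snp], slope, p_raw, float(np.clip(r2_adj, 0.0, 1.0))))
    out = pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position_cM", "slope", "p_raw", "r2_adj"]
    ).set_index("snp_id")
    return out


def holm_adjust(p_raw: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Holm step-down Bonferroni adjustment.

    Order the m raw p-values ascending; the i-th ordered adjusted value is
    max_{j <= i} min(1, (m - j + 1) p_(j)), which enforces monotonicity and
    caps at one.  NaN entries are ignored (returned as NaN, not counted in m).
    """
    p = np.asarray(p_raw, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        factors = m - np.arange(m)
        adj = np.minimum(pv[order] * factors, 1.0)
        adj = np.maximum.accumulate(adj)
        res = np.empty(m)
        res[order] = adj
        out[ok] = res
    if isinstance(p_raw, pd.Series):
        return pd.Series(out, index=p_raw.index, name="p_bon")
    return out


def declare_mtas(
    scan: pd.DataFrame,
    spec: ModelSpec,
    trait: str,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Declare marker-trait associations: SNP main effects with p_bon < threshold.

    Adds the Holm adjustment over the scanned SNPs of this application and
    returns one row per significant SNP, carrying the model provenance, the
    exotic effect (2 x slope) and the adjusted variance explained.
    """
    scan = scan.copy()
    scan["p_bon"] = holm_adjust(scan["p_raw"])
    hits = scan[scan["p_bon"] < threshold]
    return pd.DataFrame(
        {
            "trait": trait,
            "model": spec.model_id,
            "family_scope": spec.family_scope,
            "n_scope": spec.n_scope,
            "snp_id": hits.index,
            "chromosome": hits["chromosome"].to_numpy(),
            "position_cM": hits["position_cM"].to_numpy(),
            "slope": hits["slope"].to_numpy(),
            "exotic_effect": 2.0 * hits["slope"].to_numpy(),
            "p_raw": hits["p_raw"].to_numpy(),
            "p_bon": hits["p_bon"].to_numpy(),
            "r2_adj": hits["r2_adj"].to_numpy(),
        }
    ).reset_index(drop=True)


def run_all_models(
    line_means: dict[str, pd.DataFrame],
    dosages: pd.DataFrame,
    families: pd.Series,
    gmap,
    traits: list[str] | None = None,
    ratio_traits: list[str] | None = None,
    alpha: float = 0.05,
    window_cm: float = 1.0,
    criterion: str = "bic",
    return_scans: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Execute every model application and concatenate the resulting MTAs.

    ``line_means`` maps scope key -> line x trait adjusted means, with key
    "across" required and one key per N level for models 3/4.  Cofactors are
    selected separately for each trait x model scope on that scope's lines
    and means.  Deterministic given inputs.
    """
    n_levels = sorted(k for k in line_means if k != ACROSS)
    fams = sorted(pd.unique(families.loc[dosages.index]))
    if traits is None:
        traits = list(line_means[ACROSS].columns)
    ratio_traits = ratio_traits or []
    mtas, scans = [], []
    for trait in traits:
        is_ratio = trait in ratio_traits
        for spec in model_applications(fams, n_levels, ratio=is_ratio):
            means = line_means[spec.n_scope if spec.n_scope != ACROSS else ACROSS]
            if trait not in means.columns:
                raise KeyError(f"trait {trait!r} missing from scope {spec.n_scope!r} means")
            y = means[trait].dropna()
            lines = dosages.index.intersection(y.index)
            if spec.family_scope != ACROSS:
                lines = lines[families.loc[lines] == spec.family_scope]
            y = y.loc[lines]
            sub = dosages.loc[lines]
            cofs = select_cofactors(sub, y, criterion=criterion)
            scan = snp_scan(y, sub, families, gmap, cofs, spec, window_cm=window_cm)
            mta = declare_mtas(scan, spec, trait, threshold=alpha)
            mtas.append(mta)
            if return_scans:
                s = scan.reset_index()
                s.insert(0, "trait", trait)
                s.insert(1, "model", spec.model_id)
                s.insert(2, "family_scope", spec.family_scope)
                s.insert(3, "n_scope", spec.n_scope)
                s["p_bon"] = holm_adjust(s["p_raw"])
                scans.append(s)
    mta_df = pd.concat(mtas, ignore_index=True) if mtas else pd.DataFrame()
    if return_scans:
        scan_df = pd.concat(scans, ignore_index=True) if scans else pd.DataFrame()
        return mta_df, scan_df
    return mta_df
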