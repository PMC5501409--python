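"""Merge marker-trait associations into QTL and classify their stability.

MTAs of the same trait on the same chromosome are merged into one QTL when
their peak-marker positions are linked by less than 5 cM, chained by single
linkage (a < 5 cM step anywhere joins the clusters, which reproduces the
wide ranges a major locus accumulates across model applications).  Each QTL
reports its peak SNP (smallest adjusted p; ties broken by position, then
SNP id), the cM range spanned by its members, and a stability class over
families and nitrogen levels derived from the model provenance of its
member MTAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QtlRecord", "merge_mtas", "classify_stability", "summary_tables"]

ACROSS = "across"


@dataclass
class QtlRecord:
    """One QTL: a cluster of MTAs for a single trait on a single chromosome."""

    qtl_name: str
    trait: str
    chromosome: str
    peak_snp: str
    peak_position_cM: float
    range_min_cM: float
    range_max_cM: float
    exotic_effect: float
    r2_adj: float
    p_bon: float
    family_class: str
    n_class: str
    members: pd.DataFrame = field(repr=False)

    @property
    def n_members(self) -> int:
        return len(self.members)


def classify_stability(members: pd.DataFrame, families: list[str] | None = None) -> tuple[str, str]:
    """Family and N-level stability of a QTL from its member MTAs.

    A QTL is across-families if any member comes from an across-family model
    (1 or 3) or members cover both families' within-family models; otherwise
    it belongs to the single family observed.  The N-level class is analogous
    over across-N models (1, 2) and the two N levels.
    """
    if members.empty:
        raise ValueError("QTL with no member MTAs")
    fam_scopes = set(members["family_scope"])
    n_scopes = set(members["n_scope"])
    if ACROSS in fam_scopes or len(fam_scopes) > 1:
        fam_class = "across-families"
    else:
        fam_class = f"{next(iter(fam_scopes))}-only"
    if ACROSS in n_scopes or len(n_scopes) > 1:
        n_class = "across-N"
    else:
        n_class = f"{next(iter(n_scopes))}-only"
    return fam_class, n_class


def _single_linkage_clusters(positions: np.ndarray, window: float) -> np.ndarray:
    """Cluster sorted-by-position indices: new cluster when a gap >= window."""
    order = np.argsort(positions, kind="stable")
    labels = np.empty(len(positions), dtype=int)
    current = 0
    prev = None
    for idx in order:
        if prev is not None and positions[idx] - prev >= window:
            current += 1
        labels[idx] = current
        prev = positions[idx]
    return labels


def merge_mtas(
    mtas: pd.DataFrame, gmap=None, window_cm: float = 5.0, population: str = "SW84"
) -> list[QtlRecord]:
    """Merge significant MTAs into QTL by the < 5 cM single-linkage rule.

    ``mtas`` must carry trait, chromosome, position_cM, snp_id, p_bon,
    exotic_effect, r2_adj, family_scope and n_scope columns (positions may
    instead be supplied through ``gmap``).  Merging is within trait and
    chromosome only; order of input rows does not matter.  QTL names follow
    the Q<trait>.<scope>-<chromosome>[.letter] convention, where scope is the
    population name for across-family QTL or the family label otherwise.
    """
    if mtas.empty:
        return []
    mtas = mtas.copy()
    if "position_cM" not in mtas.columns or mtas["position_cM"].isna().any():
        if gmap is None:
            raise ValueError("MTAs lack positions and no map was given")
        pos = pd.Series(gmap.positions, index=gmap.snp_ids)
        chrom = pd.Series(gmap.chromosomes, index=gmap.snp_ids)
        missing = ~mtas["snp_id"].isin(pos.index)
        if missing.any():
            raise KeyError(f"MTA SNP {mtas.loc[missing, 'snp_id'].iloc[0]!r} not on map")
        mtas["position_cM"] = pos.reindex(mtas["snp_id"]).to_numpy()
        mtas["chromosome"] = chrom.reindex(mtas["snp_id"]).to_numpy()
    qtls: list[QtlRecord] = []
    for (trait, chromosome), group in mtas.groupby(["trait", "chromosome"], sort=True):
        group = group.sort_values(["position_cM", "snp_id"], kind="stable").reset_index(drop=True)
        labels = _single_linkage_clusters(group["position_cM"].to_numpy(dtype=float), window_cm)
        for lab in np.unique(labels):
            members = group[labels == lab].reset_index(drop=True)
            peak = members.sort_values(
                ["p_bon", "position_cM", "snp_id"], kind="stable"
            ).iloc[0]
            fam_class, n_class = classify_stability(members)
            scope = population if fam_class == "across-families" else fam_class[:-5]
            qtls.append(
                QtlRecord(
                    qtl_name=f"Q{trait}.{scope}-{chromosome}",
                    trait=str(trait),
                    chromosome=str(chromosome),
                    peak_snp=str(peak["snp_id"]),
                    peak_position_cM=float(peak["position_cM"]),
                    range_min_cM=float(members["position_cM"].min()),
                    range_max_cM=float(members["position_cM"].max()),
                    exotic_effect=float(peak.get("exotic_effect", np.nan)),
                    r2_adj=float(peak.get("r2_adj", np.nan)),
                    p_bon=float(peak["p_bon"]),
                    family_class=fam_class,
                    n_class=n_class,
                    members=members,
                )
            )
    # disambiguate multiple QTL of one trait on one chromosome with .a/.b letters
    by_name: dict[str, list[int]] = {}
    for i, q in enumerate(qtls):
        by_name.setdefault(f"{q.trait}:{q.chromosome}", []).append(i)
    for key, idxs in by_name.items():
        if len(idxs) > 1:
            ordered = sorted(idxs, key=lambda i: qtls[i].peak_position_cM)
            for letter, i in zip("abcdefghij", ordered):
                qtls[i].qtl_name += f".{letter}"
    return qtls


def summary_tables(
    qtls: list[QtlRecord], mtas: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate MTA counts by scope and tabulate per-QTL rows.

    Returns (cross_tab, qtl_table): the cross-tab counts MTAs by N scope
    (rows) x family scope (columns) with margins that both sum to the MTA
    total; the QTL table lists one row per QTL with peak and range details.
    """
    if mtas.empty:
        fam_cols = [ACROSS]
        cross = pd.DataFrame(0, index=[ACROSS, "sum"], columns=fam_cols + ["sum"])
    else:
        cross = pd.crosstab(mtas["n_scope"], mtas["family_scope"], margins=True, margins_name="sum")
        cross.index.name = "n_scope"
    rows = [
        {
            "qtl_name": q.qtl_name,
            "trait": q.trait,
            "chromosome": q.chromosome,
            "peak_snp": q.peak_snp,
            "position_cM": q.peak_position_cM,
            "range_cM": (
                f"{q.range_min_cM:.2f}"
                if q.range_min_cM == q.range_max_cM
                else f"{q.range_min_cM:.2f}-{q.range_max_cM:.2f}"
            ),
            "n_mtas": q.n_members,
            "exotic_effect": q.exotic_effect,
            "r2_adj": q.r2_adj,
            "p_bon": q.p_bon,
            "family_class": q.family_class,
            "n_class": q.n_class,
        }
        for q in qtls
    ]
    qtl_table = pd.DataFrame(
        rows,
        columns=[
            "qtl_name", "trait", "chromosome", "peak_snp", "position_cM",
            "range_cM", "n_mtas", "exotic_effect", "r2_adj", "p_bon",
            "family_class", "n_class",
        ],
    )
    return cross, qtl_table
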