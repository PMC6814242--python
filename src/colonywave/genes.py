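"""Gene-set selection procedures on expression matrices.

Implements the differential-expression filters and bespoke set constructions
used to characterize the BMP-treated edge population: the significance /
fold-change / abundance filter, the union of per-condition top-ranked up-
and down-regulated genes, three-set Venn overlap counts, Pearson correlation
matrices under configurable transforms, and the lineage-specificity filter
for embryo reference data.

Significance calling is pluggable: precomputed flags (e.g. from EBSeq run on
counts) are accepted as input, and a built-in fallback (Welch t-test on log2
values with Benjamini-Hochberg correction) is provided for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.01  # added to condition means before the fold-change ratio


@dataclass
class DETable:
    """Per-gene differential-expression records for one contrast.

    Columns of ``frame``: gene, fold_change (linear, treatment/reference),
    direction ('up'/'down'), significant (bool), max_abundance (max mean
    FPKM across the compared samples).
    """

    frame: pd.DataFrame
    contrast: str = ""

    def __len__(self) -> int:
        return len(self.frame)


def condition_means(expr: pd.DataFrame, condition: str) -> pd.Series:
    cols = [c for c in expr.columns if c.rsplit("_", 1)[0] == condition]
    if not cols:
        raise KeyError(f"no samples for condition {condition!r}")
    return expr[cols].mean(axis=1)


def make_de_table(
    expr: pd.DataFrame,
    treatment: str,
    reference: str,
    significant: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> DETable:
    """Build a DETable from condition means and a significance call.

    ``significant`` is a boolean Series indexed by gene (the pluggable
    external test); when None, the built-in replicate t-test fallback
    (:func:`ttest_significance`) is used.
    """
    mt = condition_means(expr, treatment)
    mr = condition_means(expr, reference)
    fc = (mt + pseudocount) / (mr + pseudocount)
    if significant is None:
        significant = ttest_significance(expr, treatment, reference)
    significant = significant.reindex(expr.index, fill_value=False)
    frame = pd.DataFrame(
        {
            "gene": expr.index,
            "fold_change": fc.values,
            "direction": np.where(fc.values >= 1.0, "up", "down"),
            "significant": significant.values.astype(bool),
            "max_abundance": np.maximum(mt.values, mr.values),
        }
    )
    return DETable(frame=frame, contrast=f"{treatment}_vs_{reference}")


def ttest_significance(
    expr: pd.DataFrame,
    treatment: str,
    reference: str,
    alpha: float = 0.05,
) -> pd.Series:
    """Welch t-test on log2(x+1) replicate values, BH-corrected at ``alpha``.

    A fallback for synthetic data only; real analyses should supply flags
    from a count-based test.
    """
    tc = [c for c in expr.columns if c.rsplit("_", 1)[0] == treatment]
    rc = [c for c in expr.columns if c.rsplit("_", 1)[0] == reference]
    lt = np.log2(expr[tc].values + 1.0)
    lr = np.log2(expr[rc].values + 1.0)
    res = sps.ttest_ind(lt, lr, axis=1, equal_var=False)
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.Series(reject, index=expr.index)


def filter_de(
    det: DETable,
    min_fold: float = 2.0,
    min_abundance: float = 1.0,
) -> DETable:
    """Retain significant genes with |log2 FC| >= log2(min_fold) and
    abundance >= min_abundance in at least one compared sample. Thresholds
    are inclusive."""
    f = det.frame
    keep = (
        f["significant"]
        & (np.abs(np.log2(f["fold_change"])) >= np.log2(min_fold) - 1e-12)
        & (f["max_abundance"] >= min_abundance)
    )
    return DETable(frame=f[keep].reset_index(drop=True), contrast=det.contrast)


def top_ranked(det: DETable, direction: str, n_top: int = 100) -> list[str]:
    """Top ``n_top`` genes of a filtered table in one direction, ranked by
    fold change (descending for up, ascending for down); fold-change ties are
    broken lexicographically by gene id for determinism."""
    f = det.frame[det.frame["direction"] == direction]
    ascending = direction == "down"
    f = f.sort_values(["fold_change", "gene"], ascending=[ascending, True])
    return f["gene"].head(n_top).tolist()


def union_top_set(
    de_tables: dict[str, DETable], n_top: int = 100
) -> tuple[set[str], dict[str, dict[str, list[str]]]]:
    """Union of per-condition top up- and down-regulated genes.

    Returns ``(union, per_condition)`` where ``per_condition[cond]`` maps
    'up'/'down' to the ranked lists actually taken. When fewer than ``n_top``
    genes are available in a direction, all of them are taken.
    """
    union: set[str] = set()
    per_condition: dict[str, dict[str, list[str]]] = {}
    for cond, det in de_tables.items():
        lists = {}
        for direction in ("up", "down"):
            lists[direction] = top_ranked(det, direction, n_top)
            union |= set(lists[direction])
        per_condition[cond] = lists
    return union, per_condition


def venn_overlap(sets: dict[str, set[str]]) -> dict[str, int]:
    """Region counts of the n-set Venn diagram.

    Keys are '&'-joined sorted subsets of set names, mapping to the number of
    genes in exactly that combination of sets (exclusive regions); the key of
    all names joined is the full intersection.
    """
    names = sorted(sets)
    out: dict[str, int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            out["&".join(combo)] = len(inside)
    return out


def intersection_count(sets: dict[str, set[str]]) -> int:
    """Size of the intersection of all sets (the Venn core)."""
    return len(set.intersection(*sets.values())) if sets else 0


def correlation_matrix(
    expr: pd.DataFrame,
    gene_set: set[str] | list[str],
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Pairwise Pearson r between samples over a gene set.

    ``transform``: 'raw' (FPKM as is), 'log2p1' (log2(x) + 1 style of the
    normalized read counts; implemented as log2(x + 1) for positivity), or
    'zscore' (per-gene z-scores of log2(x + 1)). Pairs involving a constant
    vector get NaN.
    """
    genes = [g for g in expr.index if g in set(gene_set)]
    sub = expr.loc[genes].astype(float)
    if transform == "raw":
        vals = sub
    elif transform == "log2p1":
        vals = np.log2(sub + 1.0)
    elif transform == "zscore":
        lg = np.log2(sub + 1.0)
        mu = lg.mean(axis=1)
        sd = lg.std(axis=1, ddof=0).replace(0.0, np.nan)
        vals = lg.sub(mu, axis=0).div(sd, axis=0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return vals.corr(method="pearson")


def lineage_specific_genes(
    embryo_expr: pd.DataFrame,
    de_between: pd.DataFrame,
    de_within: pd.DataFrame,
    lineages: tuple[str, ...] = ("EPI", "PE", "TE"),
    days: tuple[str, ...] = ("E5", "E6", "E7"),
    min_rpkm: float = 10.0,
    min_high_days: int = 2,
) -> pd.DataFrame:
    """Lineage-specific gene filter for embryo reference expression.

    ``embryo_expr`` columns are ``{lineage}_{day}`` mean RPKM values.
    ``de_between`` rows (gene, lineage, other_lineage, significant) mark
    genes differentially expressed (FC > 5 at FDR 0.01, decided by the
    pluggable external test) between a lineage and another at matched days;
    ``de_within`` rows (gene, lineage, significant) mark genes differentially
    expressed across that lineage's time points.

    Per lineage, a gene is selected when it is DE versus at least one other
    lineage, NOT DE across the lineage's own time points, and has
    RPKM >= ``min_rpkm`` in at least ``min_high_days`` of the lineage's time
    points. Returns a frame (gene, lineage) of the union with per-lineage
    membership.
    """
    for lin in lineages:
        for day in days:
            if f"{lin}_{day}" not in embryo_expr.columns:
                raise KeyError(f"missing time point column {lin}_{day}")
    rows = []
    for lin in lineages:
        between = set(
            de_between[
                (de_between["lineage"] == lin) & de_between["significant"]
            ]["gene"]
        )
        within = set(
            de_within[(de_within["lineage"] == lin) & de_within["significant"]][
                "gene"
            ]
        )
        cols = [f"{lin}_{d}" for d in days]
        high_days = (embryo_expr[cols] >= min_rpkm).sum(axis=1)
        for g in sorted(between - within):
            if g in embryo_expr.index and high_days.loc[g] >= min_high_days:
                rows.append({"gene": g, "lineage": lin})
    return pd.DataFrame(rows, columns=["gene", "lineage"])
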