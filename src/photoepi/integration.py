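"""Cross-omics integration statistics.

Joins the per-layer results — differentially expressed genes (DEGs),
differentially methylated promoters (DMPs), sRNA clusters and their
differential accumulation and sCTGR methylation — into the study-level
summaries: DEG x DMP overlap percentages, the 2x2 Fisher association
between differential sRNA accumulation and >= 5% differential sCTGR
methylation, promoter-vs-gene-body sRNA effects on expression
(Wilcoxon-Mann-Whitney), and functional-category distributions with the
"at least 2% of genes" display rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .stats import fisher_exact_table


@dataclass
class OverlapSummary:
    n_deg: int
    n_dmp: int
    n_both: int
    pct_dmp_that_are_deg: float
    pct_deg_with_dmp: float


def overlap_deg_dmp(deg_results, dm_calls, direction_split=True):
    """Overlap accounting between DEGs and genes with DMPs.

    *deg_results* are gene-level :class:`~photoepi.diffcounts.DifferentialResult`;
    *dm_calls* are promoter :class:`~photoepi.methylome.DMCall` rows (any
    context; region_id = gene id). A gene is a DMP gene if any context's
    promoter call is non-ns. Returns ``(OverlapSummary, per_gene_frame)``;
    the frame carries log2 fold change, per-context promoter differences and
    statuses for scatter-style output.
    """
    deg_status = {r.feature_id: r for r in deg_results}
    dm_by_gene: dict[str, list] = {}
    for c in dm_calls:
        dm_by_gene.setdefault(c.region_id, []).append(c)
    universe = set(deg_status) & set(dm_by_gene)
    if not universe:
        raise ValueError("no shared gene ids between expression and methylation results")

    deg_ids = {g for g, r in deg_status.items() if r.status != "ns"}
    dmp_ids = {g for g, calls in dm_by_gene.items() if any(c.status != "ns" for c in calls)}
    both = deg_ids & dmp_ids

    rows = []
    for g in sorted(set(deg_status) | set(dm_by_gene)):
        r = deg_status.get(g)
        row = {
            "gene_id": g,
            "log2_fc": r.log2_fc if r else np.nan,
            "deg_status": r.status if r else "untested",
        }
        for c in dm_by_gene.get(g, []):
            row[f"promoter_diff_{c.context}"] = c.diff
            row[f"promoter_status_{c.context}"] = c.status
        rows.append(row)
    frame = pd.DataFrame(rows)

    summary = OverlapSummary(
        n_deg=len(deg_ids),
        n_dmp=len(dmp_ids),
        n_both=len(both),
        pct_dmp_that_are_deg=100.0 * len(both) / len(dmp_ids) if dmp_ids else float("nan"),
        pct_deg_with_dmp=100.0 * len(both) / len(deg_ids) if deg_ids else float("nan"),
    )
    return summary, frame


@dataclass
class AssociationTable:
    """2x2 association of differential sRNA accumulation x sCTGR methylation."""

    table: np.ndarray  # [[both, acc_only], [meth_only, neither]]
    odds_ratio: float
    p: float


def srna_methylation_association(cluster_de, cluster_dm, min_diff=0.05):
    """Fisher association between differential accumulation and methylation.

    A cluster counts as differentially accumulated when its count-test status
    is non-ns, and as differentially methylated when any context's region
    call is non-ns AND the pooled |difference| reaches *min_diff* (the 5%
    floor). Clusters with no methylation coverage in any context are
    excluded. Returns an :class:`AssociationTable` (two-sided Fisher exact;
    odds ratio with Haldane 0.5 correction when a cell is zero).
    """
    de_status = {r.feature_id: r.status != "ns" for r in cluster_de}
    dm = cluster_dm.copy()
    covered = dm[dm["n_covered_c"] > 0]
    if len(covered) == 0:
        raise ValueError("no clusters with methylation coverage")
    meth_flag = (
        covered.assign(
            diff_meth=(covered["status"] != "ns")
            & (covered["diff"].abs() >= min_diff)
        )
        .groupby("region_id")["diff_meth"]
        .any()
    )
    universe = [cid for cid in meth_flag.index if cid in de_status]
    acc = np.array([de_status[c] for c in universe])
    met = np.array([meth_flag[c] for c in universe])
    table = np.array(
        [
            [(acc & met).sum(), (acc & ~met).sum()],
            [(~acc & met).sum(), (~acc & ~met).sum()],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate association table (zero margin); p set to 1")
        return AssociationTable(table=table, odds_ratio=float("nan"), p=1.0)
    orat, p = fisher_exact_table(table)
    return AssociationTable(table=table, odds_ratio=float(orat), p=float(p))


def _wmw(x, y):
    """Two-sided Wilcoxon-Mann-Whitney; exact when both n <= 8 and tie-free."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    exact = (
        len(x) <= 8 and len(y) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def gb_vs_promoter_srna(deg_results, clusters, cluster_de, min_n=3):
    """Promoter vs gene-body sRNA accumulation changes around DEGs.

    For each DEG direction (up / down), cluster log2 fold changes are split
    by compartment of the linked gene — promoter (P) vs gene body (GB) — and
    compared with a two-sided Wilcoxon-Mann-Whitney test; the complementary
    contrast (up- vs down-DEG within each compartment) is also computed,
    since either reading of the comparison may be wanted. Strata with fewer
    than *min_n* observations on either side are reported as skipped.

    Returns a DataFrame with one row per contrast.
    """
    deg_dir = {r.feature_id: r.status for r in deg_results}
    cluster_fc = {r.feature_id: r.log2_fc for r in cluster_de}

    samples: dict[tuple[str, str], list[float]] = {}
    for c in clusters:
        if c.category not in ("promoter", "gene_body") or c.linked_gene is None:
            continue
        direction = deg_dir.get(c.linked_gene)
        if direction not in ("up", "down"):
            continue
        fc = cluster_fc.get(c.cluster_id)
        if fc is None:
            continue
        key = (direction, "P" if c.category == "promoter" else "GB")
        samples.setdefault(key, []).append(fc)

    rows = []

    def _contrast(label, a_key, b_key):
        a = samples.get(a_key, [])
        b = samples.get(b_key, [])
        row = {
            "contrast": label,
            "n_a": len(a),
            "n_b": len(b),
            "median_a": float(np.median(a)) if a else np.nan,
            "median_b": float(np.median(b)) if b else np.nan,
        }
        if len(a) < min_n or len(b) < min_n:
            row.update(U=np.nan, p=np.nan, method="skipped")
        else:
            u, p, method = _wmw(a, b)
            row.update(U=u, p=p, method=method)
        rows.append(row)

    for direction in ("up", "down"):
        _contrast(f"{direction}:P_vs_GB", (direction, "P"), (direction, "GB"))
    for loc in ("P", "GB"):
        _contrast(f"{loc}:up_vs_down", ("up", loc), ("down", loc))
    return pd.DataFrame(rows)


def category_distribution(gene_set, category_map, min_fraction=0.02, labels=None):
    """Functional-category fractions with the >= 2% display rule.

    *category_map* maps gene id -> category name. Fractions are over the
    categorized genes of *gene_set*; categories below *min_fraction* are
    collapsed into "other". When *labels* (gene id -> e.g. up/down) is
    given, per-label splits of each shown category are preserved.

    Returns a DataFrame with columns category, fraction, n (and one column
    per label value when *labels* is given).
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    categorized = [g for g in gene_set if g in category_map]
    if len(categorized) < 0.5 * len(gene_set):
        warnings.warn(
            f"category map covers only {len(categorized)}/{len(gene_set)} genes"
        )
    if not categorized:
        raise ValueError("no genes covered by the category map")
    cats = pd.Series({g: category_map[g] for g in categorized})
    frac = cats.value_counts() / len(categorized)
    shown = frac[frac >= min_fraction]
    collapsed = cats.map(lambda c: c if c in shown.index else "other")
    out = (
        collapsed.value_counts()
        .rename_axis("category")
        .to_frame("n")
        .assign(fraction=lambda d: d["n"] / len(categorized))
        .reset_index()
    )
    if labels is not None:
        lab = pd.Series({g: labels.get(g, "unlabelled") for g in categorized})
        for value in sorted(lab.unique()):
            out[f"n_{value}"] = out["category"].map(
                collapsed[lab == value].value_counts()
            ).fillna(0).astype(int)
    return out.sort_values("fraction", ascending=False, ignore_index=True)
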