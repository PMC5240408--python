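"""Comparative statistics: expression specificity, GO-subset chromatin-state
enrichment clustering, domain-width comparisons, TE bimodal-mark tests and
X:A dosage-compensation ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from scipy.spatial.distance import squareform

from . import hmm as hmm_mod
from . import intervals as iv
from .containers import Cher, GenomeAnnotation, Segmentation

log = logging.getLogger(__name__)


# -- expression specificity -------------------------------------------------


def specificity(expr_vector) -> float:
    """Normalized-entropy expression specificity in [0, 1].

    ``p_i = x_i / sum(x)``; ``H = -sum p_i log2 p_i`` (0 log 0 := 0);
    ``score = 1 - H / log2(n_stages)``.  1 = expressed in a single stage,
    0 = equally expressed in all stages.  All-zero vectors are missing.
    """
    x = np.asarray(expr_vector, dtype=float)
    if x.size < 2:
        raise ValueError("specificity requires >= 2 stages")
    if np.any(x < 0):
        raise ValueError("expression values must be nonnegative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x / total
    h = float(ss.entropy(p, base=2))
    return 1.0 - h / np.log2(x.size)


def specificity_scores(expr: pd.DataFrame) -> pd.Series:
    """Per-gene specificity over the stage columns of an expression table."""
    vals = expr.to_numpy(float)
    out = np.full(len(expr), np.nan)
    totals = vals.sum(axis=1)
    ok = totals > 0
    p = vals[ok] / totals[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    out[ok] = 1.0 + terms.sum(axis=1) / np.log2(vals.shape[1])
    return pd.Series(out, index=expr.index, name="specificity")


def classify_specificity(scores, low_cut: float = 0.2, high_cut: float = 0.9) -> pd.Series:
    """``low`` (score <= 0.2), ``high`` (score >= 0.9), else ``mid``."""
    s = pd.Series(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("specificity scores must lie in [0, 1]")
    out = pd.Series("mid", index=s.index)
    out[s <= low_cut] = "low"
    out[s >= high_cut] = "high"
    return out


# -- GO subsets -------------------------------------------------------------


@dataclass
class GoSubset:
    go_term: str
    tissue: str
    activity: str  # active | silent
    gene_ids: Set[str]


def build_go_subsets(
    go_table: pd.DataFrame,
    activity_by_tissue: Mapping[str, Mapping[str, Set[str]]],
    min_parent_genes: int = 50,
    min_subset_genes: int = 10,
) -> List[GoSubset]:
    """Active/silent gene subsets per sufficiently large GO term.

    Only GO terms with >= ``min_parent_genes`` annotated genes are used;
    each is split into active and silent genes per tissue, and only splits
    with >= ``min_subset_genes`` genes are kept.  ``activity_by_tissue``
    maps tissue -> {"active": set, "silent": set}.
    """
    out: List[GoSubset] = []
    sizes = go_table.groupby("go_term")["gene_id"].nunique()
    big_terms = sizes[sizes >= min_parent_genes].index
    members = {
        term: set(grp["gene_id"])
        for term, grp in go_table[go_table["go_term"].isin(big_terms)].groupby("go_term")
    }
    for term in sorted(members):
        for tissue, activity_sets in activity_by_tissue.items():
            for activity in ("active", "silent"):
                genes = members[term] & set(activity_sets.get(activity, set()))
                if len(genes) >= min_subset_genes:
                    out.append(GoSubset(str(term), tissue, activity, genes))
    return out


def gene_anchor_intervals(
    annotation: GenomeAnnotation,
    gene_ids: Iterable[str],
    anchor: str,
    promoter_bp: int = 400,
    point_halfwidth: int = 25,
) -> Dict[str, List[Tuple[int, int]]]:
    """Per-chromosome intervals for a gene-set anchor.

    ``gene_body`` = [start, end); ``promoter`` = 400 bp upstream of TSS;
    ``TSS`` / ``TES`` = the anchor point expanded by ``point_halfwidth``
    on each side (one 50-bp window at the default).
    """
    from .annotate import define_promoters

    genes = annotation.genes.loc[list(gene_ids)]
    out: Dict[str, List[Tuple[int, int]]] = {}
    if anchor == "gene_body":
        for r in genes.itertuples():
            out.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    elif anchor == "promoter":
        proms = define_promoters(genes, annotation.chromosomes, upstream_bp=promoter_bp)
        for r in proms.itertuples():
            out.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    elif anchor in ("TSS", "TES"):
        col = "tss" if anchor == "TSS" else "tes"
        lengths = annotation.chromosomes["length"]
        for r in genes.itertuples():
            p = int(getattr(r, col))
            s = max(0, p - point_halfwidth)
            e = min(int(lengths[r.chrom]), p + point_halfwidth + 1)
            out.setdefault(r.chrom, []).append((s, e))
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return out


def go_state_enrichment(
    subsets: Sequence[GoSubset],
    seg_by_tissue: Mapping[str, Segmentation],
    annotation: GenomeAnnotation,
    anchors: Sequence[str] = ("TSS", "TES", "promoter", "gene_body"),
    promoter_bp: int = 400,
) -> pd.DataFrame:
    """Fold enrichment of every state at every (subset x anchor).

    Rows = (go_term, tissue, activity, anchor); columns = states.  Subsets
    with no mappable anchors are dropped (logged).
    """
    rows = []
    index = []
    for sub in subsets:
        seg = seg_by_tissue[sub.tissue]
        for anchor in anchors:
            feats = gene_anchor_intervals(annotation, sub.gene_ids, anchor, promoter_bp)
            if not feats:
                log.info(
                    "dropping subset %s/%s/%s at %s: no mappable anchors",
                    sub.go_term, sub.tissue, sub.activity, anchor,
                )
                continue
            fold = hmm_mod.fold_enrichment(seg, {"f": feats}, annotation)["f"]
            rows.append(fold.to_numpy())
            index.append((sub.go_term, sub.tissue, sub.activity, anchor))
    if not rows:
        return pd.DataFrame()
    idx = pd.MultiIndex.from_tuples(index, names=["go_term", "tissue", "activity", "anchor"])
    k = rows[0].size
    return pd.DataFrame(rows, index=idx, columns=[f"E{i + 1}" for i in range(k)])


def cluster_enrichments(
    table: pd.DataFrame,
    cut_height: float = 1.0,
    linkage: str = "average",
    min_finite: int = 3,
) -> pd.Series:
    """Hierarchical clustering of enrichment rows at distance 1 − Pearson r.

    Average linkage by default; the dendrogram is cut at ``cut_height``
    (rows whose cophenetic distance is <= the cut share a cluster).
    Rows with < ``min_finite`` finite values are dropped; constant rows
    (undefined correlation) get distance 1 to everything (logged).
    Cluster labels are integers numbered by first row occurrence, so the
    output is stable under row order.
    """
    if len(table) < 2:
        raise ValueError("clustering requires >= 2 rows")
    finite_ok = table.notna().sum(axis=1) >= min_finite
    if (~finite_ok).any():
        log.info("dropping %d rows with < %d finite values", int((~finite_ok).sum()), min_finite)
    tbl = table[finite_ok]
    corr = tbl.T.corr()  # pairwise-complete Pearson
    dist = 1.0 - corr.to_numpy()
    bad = ~np.isfinite(dist)
    if bad.any():
        log.info("constant/undefined correlations in %d pairs; assigned distance 1", int(bad.sum()))
        dist[bad] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = sch.linkage(squareform(dist, checks=False), method=linkage)
    raw = sch.fcluster(z, t=cut_height, criterion="distance")
    # renumber by first occurrence for stable output
    seen: Dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(seen[r])
    return pd.Series(labels, index=tbl.index, name="cluster")


# -- domain widths ----------------------------------------------------------


def adjust_widths(widths, target_resolution: int = 200) -> np.ndarray:
    """Round each width up to the nearest multiple of ``target_resolution``
    (compensates a finer segmentation grid when comparing across studies)."""
    w = np.asarray(widths, dtype=np.int64)
    if np.any(w <= 0):
        raise ValueError("widths must be positive")
    return ((w + target_resolution - 1) // target_resolution) * target_resolution


@dataclass
class WidthComparison:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    median_ratio: float  # median(b) / median(a)
    n_a: int
    n_b: int


def compare_width_distributions(a, b, exact_max_n: int = 50) -> WidthComparison:
    """Two-sided Mann-Whitney U between two width samples.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie correction.  Also reports the median-width
    ratio b/a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both width samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = ss.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return WidthComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=med_a,
        median_b=med_b,
        median_ratio=med_b / med_a if med_a else float("nan"),
        n_a=int(a.size),
        n_b=int(b.size),
    )


# -- chi-squared tests ------------------------------------------------------


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    std_residuals: np.ndarray


def pearson_chi2(table) -> ChiSquareResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    stat, p, df, expected = ss.chi2_contingency(obs, correction=False)
    if np.any(expected < 1):
        log.warning("expected cell count below 1; chi-squared approximation is weak")
    resid = (obs - expected) / np.sqrt(expected)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        observed=obs,
        expected=np.asarray(expected),
        std_residuals=resid,
    )


def te_bimodal_test(
    transposons: pd.DataFrame,
    heterochromatic: Sequence[Cher],
    active: Sequence[Cher],
    genome: Optional[GenomeAnnotation] = None,
    y_only: bool = True,
) -> Tuple[ChiSquareResult, pd.DataFrame]:
    """TE order x bimodal-mark contingency test.

    A TE is "bimodal" if it overlaps (>= 1 bp) both a heterochromatic
    region (H3K9me3) and an active-mark region (H3K4me3 or H3K36me3).
    Defaults to Y-chromosome TEs only; orders with zero TEs are dropped.
    Returns the Pearson chi-squared result (df = #orders - 1) and the
    per-order table with observed/expected bimodal counts.
    """
    tes = transposons
    if y_only:
        if genome is None:
            raise ValueError("genome annotation required for y_only filtering")
        y_chroms = set(
            genome.chromosomes.index[genome.chromosomes["chrom_class"] == "Y"]
        )
        tes = tes[tes["chrom"].isin(y_chroms)]
    if not len(tes):
        raise ValueError("no transposons to test")

    def chrom_intervals(chers: Sequence[Cher]) -> Dict[str, List[Tuple[int, int]]]:
        d: Dict[str, List[Tuple[int, int]]] = {}
        for c in chers:
            d.setdefault(c.chrom, []).append((c.start, c.end))
        return d

    het = chrom_intervals(heterochromatic)
    act = chrom_intervals(active)
    flags = []
    for chrom, grp in tes.groupby("chrom"):
        qs = list(zip(grp["start"], grp["end"]))
        h = iv.overlap_flags(qs, het.get(chrom, []))
        a = iv.overlap_flags(qs, act.get(chrom, []))
        flags.append(pd.Series(h & a, index=grp.index))
    bimodal = pd.concat(flags).reindex(tes.index)

    counts = (
        pd.DataFrame({"order": tes["order"], "bimodal": bimodal})
        .groupby("order")["bimodal"]
        .agg(bimodal="sum", total="count")
    )
    counts = counts[counts["total"] > 0]
    counts["not_bimodal"] = counts["total"] - counts["bimodal"]
    if len(counts) < 2:
        raise ValueError("need at least two TE orders with observations")
    table = counts[["bimodal", "not_bimodal"]].to_numpy()
    if (table.sum(axis=0) == 0).any():
        raise ValueError(
            "degenerate contingency table: no TE is "
            + ("bimodal" if counts["bimodal"].sum() == 0 else "non-bimodal")
        )
    result = pearson_chi2(table)
    counts["expected_bimodal"] = result.expected[:, 0]
    counts["std_residual"] = result.std_residuals[:, 0]
    return result, counts


# -- dosage compensation ----------------------------------------------------


def xa_ratio(
    expression: pd.DataFrame,
    chrom_class: pd.Series,
    tissue: Optional[str] = None,
    constitutive_only: bool = False,
    log_scale: bool = False,
) -> float:
    """Mean X-linked over mean autosomal expression among expressed genes.

    ``tissue`` selects one stage/tissue column (default: first column).
    ``constitutive_only`` restricts to genes expressed (> 0) in every
    column of the table.  ``log_scale`` averages log2 expression instead
    (ratio returned on the linear scale).
    """
    col = tissue or expression.columns[0]
    vals = expression[col]
    cls = chrom_class.reindex(expression.index)
    if constitutive_only:
        keep = (expression > 0).all(axis=1)
    else:
        keep = vals > 0
    autosomal = vals[keep & (cls == "A")]
    x_linked = vals[keep & (cls == "X")]
    if autosomal.empty or x_linked.empty:
        log.warning("xa_ratio: empty X or autosome class")
        return float("nan")
    if log_scale:
        return float(2 ** (np.log2(x_linked).mean() - np.log2(autosomal).mean()))
    return float(x_linked.mean() / autosomal.mean())


# -- paused promoters -------------------------------------------------------


def paused_promoter_genes(
    rnapii_chers: Sequence[Cher],
    silent_genes: Iterable[str],
    promoters: pd.DataFrame,
) -> Tuple[Set[str], float]:
    """Silent genes whose promoter overlaps an RNAPII-enriched region.

    Returns the gene set and its fraction of all silent genes.
    """
    silent = [g for g in silent_genes if g in promoters.index]
    if not silent:
        return set(), 0.0
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c in rnapii_chers:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    hits: Set[str] = set()
    proms = promoters.loc[silent]
    for chrom, grp in proms.groupby("chrom"):
        qs = list(zip(grp["start"], grp["end"]))
        flags = iv.overlap_flags(qs, by_chrom.get(chrom, []))
        hits.update(g for g, f in zip(grp.index, flags) if f)
    return hits, len(hits) / len(silent)


def compare_paused_fractions(
    n_paused_a: int, n_silent_a: int, n_paused_b: int, n_silent_b: int
) -> ChiSquareResult:
    """2x2 chi-squared comparing paused-promoter fractions between tissues."""
    table = np.array(
        [
            [n_paused_a, n_silent_a - n_paused_a],
            [n_paused_b, n_silent_b - n_paused_b],
        ]
    )
    return pearson_chi2(table)
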