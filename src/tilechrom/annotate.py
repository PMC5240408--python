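"""Feature universe and meta-profiles: promoters, gene categories, TSS/TES
signal profiles, candidate enhancers.

Gene categories follow the conventions of compact-genome germline ChIP
studies: expression classes (top-quartile "high" among expressed genes vs
"silent"), promoter GC deciles (HGC/LGC), trans-splicing status and
chromosome class (autosome / X / Y).  Meta-profiles average smoothed
log2 ratios in a strand-aware window around TSS or TES with a 95%
normal-approximation confidence band across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .containers import Cher, GenomeAnnotation, ProbeTrack

log = logging.getLogger(__name__)


def define_promoters(
    genes: pd.DataFrame, chromosomes: pd.DataFrame, upstream_bp: int = 400
) -> pd.DataFrame:
    """Promoter = the ``upstream_bp`` region upstream of each TSS.

    With TSS stored as the half-open boundary coordinate, a + strand gene
    gets ``[tss - upstream, tss)`` and a − strand gene ``[tss, tss + upstream)``,
    clipped at chromosome bounds.  Returns a frame indexed by gene_id with
    ``chrom, start, end``.
    """
    rows = {}
    for r in genes.itertuples():
        length = int(chromosomes.loc[r.chrom, "length"])
        if r.strand == "+":
            start, end = max(0, r.tss - upstream_bp), r.tss
        else:
            start, end = r.tss, min(length, r.tss + upstream_bp)
        if end > start:
            rows[r.Index] = {"chrom": r.chrom, "start": int(start), "end": int(end)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def gc_fraction(sequence: str) -> float:
    """(G+C) / (non-N bases); empty or all-N sequences are missing (NaN)."""
    if not sequence:
        return float("nan")
    s = sequence.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    denom = len(s) - s.count("N")
    if denom == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / denom


def categorize_genes(
    expression: pd.Series,
    annotation: GenomeAnnotation,
    gc: Optional[pd.Series] = None,
    sl_flags: Optional[pd.Series] = None,
    specificity_scores: Optional[pd.Series] = None,
    silent_threshold: float = 0.0,
    gc_decile: float = 0.10,
    specificity_cuts: Tuple[float, float] = (0.2, 0.9),
) -> pd.DataFrame:
    """Per-gene category table along five independent axes.

    ``expression`` is the per-gene level in the tissue of interest.  Genes
    without expression data are excluded (their count is logged, mirroring
    the exclusion of genes lacking expression data).  Within each axis the
    classes are mutually exclusive:

    * expression_class: ``silent`` (<= silent_threshold), ``high`` (top
      quartile among expressed genes), else ``mid``;
    * gc_class: ``HGC`` / ``LGC`` = top / bottom ``gc_decile`` of promoter
      GC (ties broken by stable gene-id order, sizes = floor(decile * n));
    * sl_class: ``trans-spliced`` / ``non``;
    * chrom_class: A / X / Y from the chromosome table;
    * specificity_class: ``low`` (<= 0.2), ``high`` (>= 0.9), else ``mid``.
    """
    genes = annotation.genes
    expr = expression.reindex(genes.index)
    missing = expr.isna()
    if missing.any():
        log.info("excluding %d genes with no expression data", int(missing.sum()))
    expr = expr[~missing]

    out = pd.DataFrame(index=expr.index)
    out.index.name = "gene_id"

    expressed = expr[expr > silent_threshold]
    cls = pd.Series("mid", index=expr.index)
    cls[expr <= silent_threshold] = "silent"
    if len(expressed):
        q75 = float(np.quantile(expressed.to_numpy(), 0.75))
        cls[(expr > silent_threshold) & (expr >= q75)] = "high"
    out["expression_class"] = cls

    if gc is not None:
        gcv = gc.reindex(out.index)
        have = gcv[gcv.notna()]
        k = int(np.floor(gc_decile * len(have)))
        order = have.sort_values(kind="stable").index  # stable: ties keep gene-id order
        gcls = pd.Series("mid", index=out.index)
        gcls[gcv.isna()] = "mid"
        if k > 0:
            gcls[order[:k]] = "LGC"
            gcls[order[len(order) - k :]] = "HGC"
        out["gc_class"] = gcls

    if sl_flags is not None:
        sl = sl_flags.reindex(out.index).fillna(False).astype(bool)
        out["sl_class"] = np.where(sl, "trans-spliced", "non")

    out["chrom_class"] = (
        genes.loc[out.index, "chrom"].map(annotation.chromosomes["chrom_class"]).to_numpy()
    )

    if specificity_scores is not None:
        sp = specificity_scores.reindex(out.index)
        low_cut, high_cut = specificity_cuts
        scls = pd.Series("mid", index=out.index)
        scls[sp <= low_cut] = "low"
        scls[sp >= high_cut] = "high"
        scls[sp.isna()] = "mid"
        out["specificity_class"] = scls

    return out


@dataclass
class MetaProfile:
    """Mean signal and 95% CI around an anchor, strand-aware offsets in bp."""

    anchor: str
    offsets: np.ndarray
    mean: np.ndarray
    ci95: np.ndarray
    n_genes: int
    filter_counts: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "ci95": self.ci95})


def _intergenic_ok(genes: pd.DataFrame, chromosomes: pd.DataFrame, min_bp: int) -> pd.Series:
    """Both flanks (to nearest neighbouring gene or chromosome end) >= min_bp."""
    ok = pd.Series(False, index=genes.index)
    for chrom, grp in genes.groupby("chrom"):
        grp = grp.sort_values("start")
        length = int(chromosomes.loc[chrom, "length"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        prev_end = np.concatenate([[0], ends[:-1]])
        next_start = np.concatenate([starts[1:], [length]])
        good = (starts - prev_end >= min_bp) & (next_start - ends >= min_bp)
        ok.loc[grp.index] = good
    return ok


def metaprofile(
    track: ProbeTrack,
    annotation: GenomeAnnotation,
    gene_ids: Optional[Iterable[str]] = None,
    anchor: str = "TSS",
    window_bp: int = 1000,
    min_gene_bp: int = 1000,
    min_intergenic_bp: int = 1100,
    bin_bp: int = 50,
) -> MetaProfile:
    """Mean smoothed log2 ratio per strand-aware offset around TSS or TES.

    Genes shorter than ``min_gene_bp`` or with either flanking intergenic
    space below ``min_intergenic_bp`` are excluded; offsets are negative
    upstream of the anchor in the direction of transcription and binned at
    ``bin_bp``.  The CI half-width is 1.96 x SE of the per-gene bin means.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    genes = annotation.genes
    if gene_ids is not None:
        genes = genes.loc[list(gene_ids)]
    n_in = len(genes)
    long_enough = (genes["end"] - genes["start"]) >= min_gene_bp
    spaced = _intergenic_ok(annotation.genes, annotation.chromosomes, min_intergenic_bp)
    spaced = spaced.reindex(genes.index).fillna(False)
    kept = genes[long_enough & spaced]
    counts = {
        "n_in": n_in,
        "n_kept": len(kept),
        "n_short": int((~long_enough).sum()),
        "n_crowded": int((long_enough & ~spaced).sum()),
    }
    if not len(kept):
        raise ValueError(f"no genes pass the profile filters: {counts}")

    half = window_bp // 2
    offsets = np.arange(-half, half + 1, bin_bp)
    sums = np.zeros(offsets.size)
    sqs = np.zeros(offsets.size)
    ns = np.zeros(offsets.size)

    for r in kept.itertuples():
        if r.chrom not in track.chroms:
            continue
        pos, val = track.chroms[r.chrom]
        apos = r.tss if anchor == "TSS" else r.tes
        lo = np.searchsorted(pos, apos - half, side="left")
        hi = np.searchsorted(pos, apos + half, side="right")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        v = val[lo:hi]
        rel = (p - apos) if r.strand == "+" else (apos - p)
        keep = np.isfinite(v) & (np.abs(rel) <= half)
        if not keep.any():
            continue
        bins = np.rint(rel[keep] / bin_bp).astype(int) + half // bin_bp
        # per-gene bin means first, then aggregate across genes
        gene_sum = np.bincount(bins, weights=v[keep], minlength=offsets.size)
        gene_n = np.bincount(bins, minlength=offsets.size)
        with np.errstate(invalid="ignore"):
            gene_mean = gene_sum / gene_n
        hit = gene_n > 0
        sums[hit] += gene_mean[hit]
        sqs[hit] += gene_mean[hit] ** 2
        ns[hit] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / ns
        var = sqs / ns - mean**2
        var = np.clip(var, 0.0, None)
        se = np.sqrt(var / np.where(ns > 1, ns, np.nan))
    ci = 1.96 * se
    ci[ns <= 1] = 0.0
    return MetaProfile(
        anchor=anchor,
        offsets=offsets,
        mean=mean,
        ci95=ci,
        n_genes=len(kept),
        filter_counts=counts,
    )


def candidate_enhancers(
    h3k4me1: Sequence[Cher],
    h3k27ac: Sequence[Cher],
    p300: Sequence[Cher],
    tss_positions: Mapping[str, Sequence[int]],
    exclusion_bp: int = 0,
) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """Tiered enhancer candidates.

    tier1 = H3K4me1 chers not overlapping any annotated TSS (the TSS point
    expanded by ``exclusion_bp`` on both sides); tier2 = tier1 ∩ H3K27ac;
    tier3 = tier2 ∩ p300 (coordinates are the intersections).  The tiers
    are nested as point sets: tier3 ⊆ tier2 ⊆ tier1.
    """

    def per_chrom(chers: Sequence[Cher]) -> Dict[str, List[Tuple[int, int]]]:
        d: Dict[str, List[Tuple[int, int]]] = {}
        for c in chers:
            d.setdefault(c.chrom, []).append((c.start, c.end))
        return d

    me1 = per_chrom(h3k4me1)
    ac = per_chrom(h3k27ac)
    p3 = per_chrom(p300)
    tss_iv = {
        chrom: [(int(p) - exclusion_bp, int(p) + exclusion_bp + 1) for p in ps]
        for chrom, ps in tss_positions.items()
    }

    tier1: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, regions in me1.items():
        flags = iv.overlap_flags(regions, tss_iv.get(chrom, []))
        keep = [r for r, hit in zip(regions, flags) if not hit]
        if keep:
            tier1[chrom] = iv.merge(keep)
    tier2 = {
        chrom: iv.intersect(regions, ac.get(chrom, []))
        for chrom, regions in tier1.items()
    }
    tier2 = {c: r for c, r in tier2.items() if r}
    tier3 = {
        chrom: iv.intersect(regions, p3.get(chrom, []))
        for chrom, regions in tier2.items()
    }
    tier3 = {c: r for c, r in tier3.items() if r}
    return {"tier1": tier1, "tier2": tier2, "tier3": tier3}


def tier_counts(tiers: Mapping[str, Mapping[str, Sequence[Tuple[int, int]]]]) -> Dict[str, int]:
    return {t: sum(len(r) for r in d.values()) for t, d in tiers.items()}
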