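"""Synthetic compact genome, planted chromatin states and tiling-array tracks.

The generator emulates the data regime of a NimbleGen-style two-channel
tiling array over an ultra-compact chordate genome: ~50-bp probe spacing,
genes with very short introns and intergenic spaces, a quarter of genes in
operons, trans-splicing, transposable elements concentrated on the
gene-poor Y chromosome, and sex chromosomes (A/X/Y classes).

Ground truth is planted on the 50-bp binarization grid: a hidden Markov
chain over K states is sampled per chromosome, per-window mark presence is
drawn from per-state Bernoulli emission probabilities, and probe-level
log2 ratios are the planted two-component Gaussian signal (present vs
absent mean) plus independent replicate noise.  Everything is
deterministic under ``SimConfig.seed`` (named substreams are derived from
the single global seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CHROM_CLASSES, GenomeAnnotation, ProbeTrack

log = logging.getLogger(__name__)

TE_ORDERS = ("DIRS", "LTR", "LINE", "Mariner", "MITE", "MAV", "PLE", "REP", "Env")

DEFAULT_MARKS = (
    "H3K4me3",
    "H3K27ac",
    "H3K36me3",
    "H3K36me2",
    "H3K9me3",
    "H3K27me3",
    "H4K20me3",
    "H3K79me3",
)

# substream tags for the single-global-seed scheme
_GENOME, _STATES, _TRACKS, _EXPR, _GO = 11, 22, 33, 44, 55


def default_transitions(k: int, self_prob: float = 0.9) -> np.ndarray:
    """Sticky transition matrix: mean domain length 1/(1-self_prob) windows."""
    if k == 1:
        return np.ones((1, 1))
    a = np.full((k, k), (1.0 - self_prob) / (k - 1))
    np.fill_diagonal(a, self_prob)
    return a


def default_emissions(k: int, m: int, lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    """Well-separated emission matrix with entries in {lo, hi}.

    Mark ``j`` is 'on' (probability hi) in state ``j % k``, giving distinct
    binary codes per state for k <= m.
    """
    e = np.full((k, m), lo)
    for j in range(m):
        e[j % k, j] = hi
    return e


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and arrays.

    Defaults describe a 1-Mb toy genome in three chromosomes (autosome, X,
    Y), 50-bp probe spacing and binarization windows, 8 marks, a 5-state
    ground-truth chain with sticky transitions (mean domain ~10 windows =
    500 bp, matching the compact domain regime), log2-ratio signal means
    2.0 (enriched) / 0.0 (background) with sd 0.5, and two replicates.
    """

    chrom_names: Tuple[str, ...] = ("chr1", "chrX", "chrY")
    chrom_lengths: Tuple[int, ...] = (500_000, 300_000, 200_000)
    chrom_classes: Tuple[str, ...] = ("A", "X", "Y")
    probe_spacing: int = 50
    window_bp: int = 50
    n_marks: int = 8
    mark_names: Optional[Tuple[str, ...]] = None
    n_states_true: int = 5
    true_transitions: Optional[np.ndarray] = None
    true_emissions: Optional[np.ndarray] = None
    signal_mean_present: float = 2.0
    signal_mean_absent: float = 0.0
    noise_sd: float = 0.5
    n_replicates: int = 2
    tissues: Tuple[str, ...] = ("ovary", "testis")
    seed: int = 0
    # genome geometry (compact defaults: intron peak ~47 bp, short intergenic)
    n_genes: Optional[int] = None
    mean_exon_bp: int = 150
    mean_intron_bp: int = 47
    exons_per_gene: int = 4
    mean_intergenic_bp: int = 400
    operon_fraction: float = 0.25
    operon_gap_bp: int = 60
    trans_spliced_fraction: float = 0.39
    te_density: float = 2e-5  # TEs per bp on class-A chromosomes
    te_density_multipliers: Dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "X": 1.0, "Y": 10.0}
    )

    def __post_init__(self) -> None:
        if self.mark_names is None:
            base = list(DEFAULT_MARKS)
            while len(base) < self.n_marks:
                base.append(f"mark{len(base) + 1}")
            self.mark_names = tuple(base[: self.n_marks])
        if self.true_transitions is None:
            self.true_transitions = default_transitions(self.n_states_true)
        if self.true_emissions is None:
            self.true_emissions = default_emissions(self.n_states_true, self.n_marks)
        self.true_transitions = np.asarray(self.true_transitions, dtype=float)
        self.true_emissions = np.asarray(self.true_emissions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (
            len(self.chrom_names) == len(self.chrom_lengths) == len(self.chrom_classes)
        ):
            raise ValueError("chromosome name/length/class tuples differ in length")
        if any(c not in CHROM_CLASSES for c in self.chrom_classes):
            raise ValueError(f"chromosome classes must be in {CHROM_CLASSES}")
        if self.probe_spacing <= 0 or self.window_bp <= 0:
            raise ValueError("probe_spacing and window_bp must be positive")
        if any(l < 10 * self.probe_spacing for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 10 x probe_spacing")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        a = self.true_transitions
        if a.shape != (self.n_states_true, self.n_states_true):
            raise ValueError("true_transitions must be K x K")
        if not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true_transitions rows must sum to 1")
        e = self.true_emissions
        if e.shape != (self.n_states_true, self.n_marks):
            raise ValueError("true_emissions must be K x M")
        if e.min() < 0 or e.max() > 1:
            raise ValueError("true_emissions entries must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def n_windows(self, chrom_length: int) -> int:
        return chrom_length // self.window_bp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_transitions"] = self.true_transitions.tolist()
        d["true_emissions"] = self.true_emissions.tolist()
        return d


@dataclass
class PlantedTruth:
    """Ground truth on the window grid for one tissue."""

    tissue: str
    window_bp: int
    state_path: Dict[str, np.ndarray]  # chrom -> per-window state index
    mark_presence: Dict[str, np.ndarray]  # chrom -> (n_windows, n_marks) uint8

    @property
    def n_windows(self) -> int:
        return int(sum(s.size for s in self.state_path.values()))

    def state_frequencies(self, n_states: int) -> np.ndarray:
        counts = np.zeros(n_states)
        for s in self.state_path.values():
            counts += np.bincount(s, minlength=n_states)
        return counts / max(1, self.n_windows)


def _rng(cfg_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed)] + [int(t) for t in tags])


def generate_genome(cfg: SimConfig) -> GenomeAnnotation:
    """Place compact gene models, operons and TEs on the configured chromosomes."""
    cfg.validate()
    rng = _rng(cfg.seed, _GENOME)
    chrom_df = pd.DataFrame(
        {"length": list(cfg.chrom_lengths), "chrom_class": list(cfg.chrom_classes)},
        index=pd.Index(cfg.chrom_names, name="chrom"),
    )

    genes = []
    gene_counter = 0
    operon_counter = 0
    budget = cfg.n_genes if cfg.n_genes is not None else np.inf

    for chrom, length, cls in zip(cfg.chrom_names, cfg.chrom_lengths, cfg.chrom_classes):
        # the Y is gene-poor: stretch intergenic space
        gap_mean = cfg.mean_intergenic_bp * (8.0 if cls == "Y" else 1.0)
        cursor = 0
        while gene_counter < budget:
            in_operon = rng.random() < cfg.operon_fraction
            n_in_unit = int(rng.integers(2, 5)) if in_operon else 1
            gap = int(rng.exponential(gap_mean)) + 50
            strand = "+" if rng.random() < 0.5 else "-"
            operon_id = None
            if in_operon:
                operon_counter += 1
                operon_id = f"op{operon_counter:04d}"
            unit = []
            pos = cursor + gap
            for i in range(n_in_unit):
                n_ex = max(1, int(rng.poisson(cfg.exons_per_gene - 1)) + 1)
                exons = rng.exponential(cfg.mean_exon_bp, size=n_ex).astype(int) + 30
                introns = (
                    rng.exponential(cfg.mean_intron_bp, size=max(0, n_ex - 1)).astype(int)
                    + 25
                )
                glen = int(exons.sum() + introns.sum())
                start, end = pos, pos + glen
                unit.append((start, end, strand, operon_id))
                pos = end + cfg.operon_gap_bp
            if unit[-1][1] > length - 50:
                break
            for start, end, strand, op in unit:
                if gene_counter >= budget:
                    break
                gene_counter += 1
                gid = f"g{gene_counter:05d}"
                tss = start if strand == "+" else end
                tes = end if strand == "+" else start
                trans_spliced = op is not None or rng.random() < max(
                    0.0,
                    (cfg.trans_spliced_fraction - cfg.operon_fraction)
                    / max(1e-9, 1.0 - cfg.operon_fraction),
                )
                genes.append(
                    dict(
                        gene_id=gid,
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        tss=tss,
                        tes=tes,
                        operon_id=op,
                        trans_spliced=bool(trans_spliced),
                    )
                )
            cursor = unit[-1][1]
        if cfg.n_genes is not None and gene_counter >= cfg.n_genes:
            # keep remaining chromosomes gene-free once the requested count is met
            pass

    gene_df = pd.DataFrame(genes)
    if len(gene_df):
        gene_df = gene_df.set_index("gene_id")
    else:
        gene_df = pd.DataFrame(
            columns=["chrom", "strand", "start", "end", "tss", "tes", "operon_id", "trans_spliced"]
        )
        gene_df.index.name = "gene_id"
    if cfg.n_genes is not None and len(gene_df) < cfg.n_genes:
        log.warning(
            "requested %d genes but only %d fit in the genome", cfg.n_genes, len(gene_df)
        )

    tes = []
    order_weights = np.array([2.0, 4.0, 1.0, 1.0, 1.5, 0.5, 0.5, 1.0, 1.0])
    order_weights = order_weights / order_weights.sum()
    for chrom, length, cls in zip(cfg.chrom_names, cfg.chrom_lengths, cfg.chrom_classes):
        dens = cfg.te_density * cfg.te_density_multipliers.get(cls, 1.0)
        n_te = int(rng.poisson(dens * length))
        for _ in range(n_te):
            tlen = int(rng.integers(300, 3000))
            start = int(rng.integers(0, max(1, length - tlen)))
            order = str(rng.choice(TE_ORDERS, p=order_weights))
            tes.append(dict(chrom=chrom, start=start, end=start + tlen, order=order))
    te_df = pd.DataFrame(tes, columns=["chrom", "start", "end", "order"])

    return GenomeAnnotation(chromosomes=chrom_df, genes=gene_df, transposons=te_df)


def plant_states(cfg: SimConfig, tissue_index: int = 0) -> PlantedTruth:
    """Sample the hidden state path and per-window mark presence for one tissue."""
    cfg.validate()
    rng = _rng(cfg.seed, _STATES, tissue_index)
    k = cfg.n_states_true
    cum = np.cumsum(cfg.true_transitions, axis=1)
    state_path: Dict[str, np.ndarray] = {}
    mark_presence: Dict[str, np.ndarray] = {}
    for chrom, length in zip(cfg.chrom_names, cfg.chrom_lengths):
        w = cfg.n_windows(length)
        u = rng.random(w)
        path = np.empty(w, dtype=np.int64)
        if w:
            path[0] = rng.integers(k)
            for t in range(1, w):
                path[t] = np.searchsorted(cum[path[t - 1]], u[t], side="right")
        state_path[chrom] = path
        probs = cfg.true_emissions[path]  # (w, M)
        mark_presence[chrom] = (rng.random(probs.shape) < probs).astype(np.uint8)
    tissue = cfg.tissues[tissue_index] if tissue_index < len(cfg.tissues) else f"t{tissue_index}"
    return PlantedTruth(
        tissue=tissue, window_bp=cfg.window_bp, state_path=state_path, mark_presence=mark_presence
    )


def simulate_tracks(
    truth: PlantedTruth, cfg: SimConfig, tissue_index: int = 0
) -> Dict[Tuple[str, int], ProbeTrack]:
    """Noisy replicated probe tracks for every mark of one tissue.

    Returns ``{(mark_name, replicate_index): ProbeTrack}``.  Replicates
    share the planted truth and use independent noise substreams.
    """
    cfg.validate()
    out: Dict[Tuple[str, int], ProbeTrack] = {}
    delta = cfg.signal_mean_present - cfg.signal_mean_absent
    for mi, mark in enumerate(cfg.mark_names):
        for rep in range(cfg.n_replicates):
            rng = _rng(cfg.seed, _TRACKS, tissue_index, mi, rep)
            chroms = {}
            for chrom, length in zip(cfg.chrom_names, cfg.chrom_lengths):
                w = cfg.n_windows(length)
                pos = np.arange(0, w * cfg.window_bp, cfg.probe_spacing, dtype=np.int64)
                widx = np.minimum(pos // cfg.window_bp, max(0, w - 1))
                present = truth.mark_presence[chrom][widx, mi].astype(float)
                vals = cfg.signal_mean_absent + present * delta
                if cfg.noise_sd > 0:
                    vals = vals + rng.normal(0.0, cfg.noise_sd, size=vals.shape)
                chroms[chrom] = (pos, vals)
            sid = f"{truth.tissue}_{mark}_rep{rep + 1}"
            out[(mark, rep)] = ProbeTrack(sample_id=sid, chroms=chroms)
    return out


def simulate_expression(
    annotation: GenomeAnnotation,
    n_stages: int = 10,
    profile: Optional[Dict[str, str]] = None,
    class_fractions: Optional[Dict[str, float]] = None,
    stage_names: Optional[Sequence[str]] = None,
    base_level: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x stage expression with controlled specificity classes.

    ``profile`` maps gene_id to a target specificity class: ``low``
    (uniform across stages, normalized-entropy specificity exactly 0),
    ``high`` (one-hot, specificity exactly 1) or ``mid`` (mass split over
    two stages).  Genes absent from ``profile`` are drawn from
    ``class_fractions`` (default 40/40/20 low/mid/high).
    """
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    rng = _rng(seed, _EXPR)
    if stage_names is None:
        stage_names = [f"stage{i + 1}" for i in range(n_stages)]
    if len(stage_names) != n_stages:
        raise ValueError("stage_names length must equal n_stages")
    fracs = class_fractions or {"low": 0.4, "mid": 0.4, "high": 0.2}
    classes = list(fracs)
    probs = np.array([fracs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    rows = {}
    for gid in annotation.genes.index:
        cls = (profile or {}).get(gid) or str(rng.choice(classes, p=probs))
        level = float(rng.lognormal(np.log(base_level), 1.0))
        vec = np.zeros(n_stages)
        if cls == "low":
            vec[:] = level
        elif cls == "high":
            vec[int(rng.integers(n_stages))] = level * n_stages
        elif cls == "mid":
            picks = rng.choice(n_stages, size=2, replace=False)
            vec[picks] = level * n_stages / 2.0
        else:
            raise ValueError(f"unknown specificity class {cls!r}")
        rows[gid] = vec
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(stage_names))
    df.index.name = "gene_id"
    return df


def simulate_go_annotation(
    annotation: GenomeAnnotation,
    n_terms: int = 20,
    mean_term_size: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy gene -> GO-term table (columns ``gene_id, go_term``)."""
    rng = _rng(seed, _GO)
    gene_ids = np.asarray(annotation.genes.index)
    rows = []
    for t in range(n_terms):
        size = max(5, int(rng.poisson(mean_term_size)))
        size = min(size, gene_ids.size)
        members = rng.choice(gene_ids, size=size, replace=False)
        for g in members:
            rows.append((str(g), f"GO:{t + 1:07d}"))
    return pd.DataFrame(rows, columns=["gene_id", "go_term"])


def simulate_dosage_expression(
    n_per_class: int = 500,
    x_factor: float = 1.0,
    sigma: float = 0.5,
    n_stages: int = 5,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Lognormal expression for X-linked vs autosomal gene cohorts.

    X-linked genes are scaled by ``x_factor`` in every stage (a 2-fold
    downregulation is ``x_factor=0.5``).  Returns the expression table and
    the per-gene chromosome class.
    """
    rng = _rng(seed, _EXPR, 1)
    ids = [f"A{i:04d}" for i in range(n_per_class)] + [f"X{i:04d}" for i in range(n_per_class)]
    cls = pd.Series(["A"] * n_per_class + ["X"] * n_per_class, index=ids, name="chrom_class")
    vals = rng.lognormal(mean=0.0, sigma=sigma, size=(2 * n_per_class, n_stages))
    vals[n_per_class:] *= x_factor
    df = pd.DataFrame(vals, index=ids, columns=[f"stage{i + 1}" for i in range(n_stages)])
    df.index.name = "gene_id"
    return df, cls
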