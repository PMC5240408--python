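"""Core in-memory containers shared across the pipeline.

Coordinate conventions used throughout the package:

* all genomic intervals are 0-based, half-open ``[start, end)``;
* probe positions are 0-based base-pair offsets;
* the TSS of a gene is stored as the half-open boundary coordinate flanking
  its first transcribed base (``start`` on the + strand, ``end`` on the −
  strand), and symmetrically for the TES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

CHROM_CLASSES = ("A", "X", "Y")


@dataclass
class ProbeTrack:
    """Per-sample sorted probe positions with log2-ratio values.

    ``chroms`` maps chromosome name to ``(positions, values)`` where
    positions are strictly increasing int64 and values are float64 with
    NaN marking missing probes.
    """

    sample_id: str
    chroms: Dict[str, Tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (pos, val) in self.chroms.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.shape != val.shape:
                raise ValueError(f"{chrom}: positions/values length mismatch")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: probe positions must be strictly increasing")
            if np.any(np.isinf(val)):
                raise ValueError(f"{chrom}: probe values must be finite or NaN")
            clean[chrom] = (pos, val)
        self.chroms = clean

    @property
    def n_probes(self) -> int:
        return int(sum(p.size for p, _ in self.chroms.values()))

    def finite_values(self) -> np.ndarray:
        """All non-missing values, concatenated across chromosomes."""
        if not self.chroms:
            return np.empty(0)
        v = np.concatenate([val for _, val in self.chroms.values()])
        return v[np.isfinite(v)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"chrom": chrom, "pos": pos, "value": val})
            for chrom, (pos, val) in self.chroms.items()
        ]
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "value"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str) -> "ProbeTrack":
        chroms = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            chroms[str(chrom)] = (
                grp["pos"].to_numpy(np.int64),
                grp["value"].to_numpy(np.float64),
            )
        return cls(sample_id=sample_id, chroms=chroms)


@dataclass
class Cher:
    """A ChIP-enriched region: ``[start, end)`` spanning >= min qualifying probes."""

    chrom: str
    start: int
    end: int
    n_probes: int
    score: float
    quantile_level: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cher end must exceed start")
        if self.n_probes < 1:
            raise ValueError("cher must contain at least one probe")


def chers_to_frame(chers: List[Cher]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_probes", "score", "quantile_level", "sample_id"]
    if not chers:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.__dict__ for c in chers])[cols]


def frame_to_chers(df: pd.DataFrame) -> List[Cher]:
    return [
        Cher(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            n_probes=int(r.n_probes),
            score=float(r.score),
            quantile_level=float(r.quantile_level),
            sample_id=str(r.sample_id),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class GenomeAnnotation:
    """The feature universe: chromosomes (with A/X/Y class), genes, TEs.

    ``chromosomes``: index = name, columns ``length`` (bp), ``chrom_class``.
    ``genes``: index = gene_id, columns ``chrom, strand, start, end, tss,
    tes, operon_id, trans_spliced``.
    ``transposons``: columns ``chrom, start, end, order``.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame
    transposons: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.chromosomes["chrom_class"]) - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes: {bad}")
        if len(self.genes):
            lengths = self.chromosomes["length"]
            for r in self.genes.itertuples():
                if r.start < 0 or r.end > lengths[r.chrom] or r.end <= r.start:
                    raise ValueError(f"gene {r.Index} outside chromosome bounds")
                exp_tss = r.start if r.strand == "+" else r.end
                if r.tss != exp_tss:
                    raise ValueError(f"gene {r.Index}: TSS inconsistent with strand")

    @property
    def genome_length(self) -> int:
        return int(self.chromosomes["length"].sum())

    def class_lengths(self) -> Dict[str, int]:
        """Total bp per chromosome class, plus ``genome``."""
        out = {"genome": self.genome_length}
        grouped = self.chromosomes.groupby("chrom_class")["length"].sum()
        for cls, n in grouped.items():
            out[str(cls)] = int(n)
        return out

    def chrom_class_of(self) -> pd.Series:
        return self.chromosomes["chrom_class"]


@dataclass
class BinaryMatrix:
    """Genome tiled into fixed windows x mark presence calls, per tissue.

    ``data`` maps chromosome to a ``(n_windows, n_marks)`` uint8 array;
    n_windows = floor(chrom_length / window_bp) (partial trailing windows
    are dropped).
    """

    tissue: str
    window_bp: int
    mark_names: List[str]
    data: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.uint8)
            if arr.ndim != 2 or arr.shape[1] != len(self.mark_names):
                raise ValueError(f"{chrom}: binary matrix shape mismatch")
            if arr.size and arr.max() > 1:
                raise ValueError(f"{chrom}: entries must be 0/1")
            self.data[chrom] = arr

    @property
    def n_windows(self) -> int:
        return int(sum(a.shape[0] for a in self.data.values()))

    def sequences(self) -> List[np.ndarray]:
        """Per-chromosome observation sequences in sorted chromosome order."""
        return [self.data[c] for c in sorted(self.data)]


@dataclass
class Segmentation:
    """Per-window decoded chromatin state and its max posterior, per tissue."""

    tissue: str
    n_states: int
    window_bp: int
    states: Dict[str, np.ndarray]
    posterior: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, s in self.states.items():
            s = np.asarray(s, dtype=np.int64)
            if s.size and (s.min() < 0 or s.max() >= self.n_states):
                raise ValueError(f"{chrom}: state index out of range")
            self.states[chrom] = s

    @property
    def n_windows(self) -> int:
        return int(sum(s.size for s in self.states.values()))

    def domain_widths(self) -> Dict[int, np.ndarray]:
        """Per-state widths (bp) of maximal constant-state runs."""
        out: Dict[int, list] = {k: [] for k in range(self.n_states)}
        for s in self.states.values():
            if s.size == 0:
                continue
            change = np.flatnonzero(np.diff(s)) + 1
            bounds = np.concatenate([[0], change, [s.size]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                out[int(s[a])].append((b - a) * self.window_bp)
        return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}
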