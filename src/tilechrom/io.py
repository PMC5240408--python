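"""Readers and writers for the pipeline's plain-text stage products.

Formats: TSV probe tracks (``chrom  pos  value`` or raw two-channel
``chrom  pos  cy5  cy3``), GFF3 annotation (genes with operon /
trans-splicing attributes, TEs with ``te_order``), chromosome table TSV,
BED for chers / segmentations / planted truth, the chromHMM binarized
text dialect for binary matrices, and JSON/flat-text model dumps.  All
coordinates are written 0-based half-open (BED-style) except GFF3, which
uses its native 1-based inclusive convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BinaryMatrix,
    Cher,
    GenomeAnnotation,
    ProbeTrack,
    Segmentation,
    chers_to_frame,
    frame_to_chers,
)
from .sim import PlantedTruth


# -- tracks -----------------------------------------------------------------


def write_track(track: ProbeTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_track(path, sample_id: Optional[str] = None) -> ProbeTrack:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"track file must have columns {sorted(required)}")
    return ProbeTrack.from_frame(df, sample_id=sample_id or Path(path).stem)


def read_raw_two_channel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "cy5", "cy3"}
    if not required.issubset(df.columns):
        raise ValueError(f"raw file must have columns {sorted(required)}")
    return df


# -- annotation -------------------------------------------------------------


def write_chrom_table(annotation: GenomeAnnotation, path) -> None:
    df = annotation.chromosomes.reset_index()
    df.columns = ["chrom", "length", "chrom_class"]
    df.to_csv(path, sep="\t", index=False)


def read_chrom_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("chrom")
    return df[["length", "chrom_class"]]


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for chrom, row in annotation.chromosomes.iterrows():
        lines.append(f"##sequence-region {chrom} 1 {int(row['length'])}")
    for r in annotation.genes.itertuples():
        attrs = [f"ID={r.Index}"]
        if r.operon_id is not None and not (isinstance(r.operon_id, float) and np.isnan(r.operon_id)):
            attrs.append(f"operon_id={r.operon_id}")
        attrs.append(f"trans_spliced={'true' if r.trans_spliced else 'false'}")
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    "tilechrom",
                    "gene",
                    str(r.start + 1),
                    str(r.end),
                    ".",
                    r.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    for i, r in enumerate(annotation.transposons.itertuples()):
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    "tilechrom",
                    "transposable_element",
                    str(r.start + 1),
                    str(r.end),
                    ".",
                    ".",
                    ".",
                    f"ID=te{i + 1:05d};te_order={r.order}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(gff_path, chrom_table_path) -> GenomeAnnotation:
    chroms = read_chrom_table(chrom_table_path)
    genes = []
    tes = []
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        start, end = int(f[3]) - 1, int(f[4])
        if f[2] == "gene":
            strand = f[6]
            genes.append(
                dict(
                    gene_id=attrs["ID"],
                    chrom=f[0],
                    strand=strand,
                    start=start,
                    end=end,
                    tss=start if strand == "+" else end,
                    tes=end if strand == "+" else start,
                    operon_id=attrs.get("operon_id"),
                    trans_spliced=attrs.get("trans_spliced") == "true",
                )
            )
        elif f[2] == "transposable_element":
            tes.append(dict(chrom=f[0], start=start, end=end, order=attrs["te_order"]))
    gene_df = pd.DataFrame(genes)
    if len(gene_df):
        gene_df = gene_df.set_index("gene_id")
    else:
        gene_df = pd.DataFrame(
            columns=["chrom", "strand", "start", "end", "tss", "tes", "operon_id", "trans_spliced"]
        )
        gene_df.index.name = "gene_id"
    te_df = pd.DataFrame(tes, columns=["chrom", "start", "end", "order"])
    return GenomeAnnotation(chromosomes=chroms, genes=gene_df, transposons=te_df)


# -- expression / categories ------------------------------------------------


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6g")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# -- planted truth ----------------------------------------------------------


def write_truth_bed(truth: PlantedTruth, path) -> None:
    rows = []
    for chrom in sorted(truth.state_path):
        states = truth.state_path[chrom]
        for w, s in enumerate(states):
            rows.append((chrom, w * truth.window_bp, (w + 1) * truth.window_bp, f"S{int(s)}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# -- chers ------------------------------------------------------------------


def write_chers(chers: Sequence[Cher], bed_path, tsv_path=None) -> None:
    """BED6 (score browser-scaled to 0-1000) plus a full-precision TSV sidecar."""
    lines = []
    for c in sorted(chers, key=lambda c: (c.chrom, c.start)):
        bed_score = int(round(1000 * min(1.0, c.score / 5.0))) if np.isfinite(c.score) else 0
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample_id}\t{max(0, bed_score)}\t."
        )
    Path(bed_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if tsv_path is not None:
        chers_to_frame(list(chers)).to_csv(tsv_path, sep="\t", index=False)


def read_chers(tsv_path) -> List[Cher]:
    return frame_to_chers(pd.read_csv(tsv_path, sep="\t"))


# -- binary matrices (chromHMM dialect) -------------------------------------


def write_binary_matrix(matrix: BinaryMatrix, outdir) -> List[Path]:
    """One file per chromosome: two header lines (tissue+chrom, mark names)
    then tab-separated 0/1 rows — the chromHMM binarized text dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom in sorted(matrix.data):
        p = outdir / f"{matrix.tissue}_{chrom}_binary.txt"
        with open(p, "w") as fh:
            fh.write(f"{matrix.tissue}\t{chrom}\n")
            fh.write("\t".join(matrix.mark_names) + "\n")
            np.savetxt(fh, matrix.data[chrom], fmt="%d", delimiter="\t")
        paths.append(p)
    return paths


def read_binary_matrix(paths: Sequence, window_bp: int = 50) -> BinaryMatrix:
    tissue = None
    marks: Optional[List[str]] = None
    data: Dict[str, np.ndarray] = {}
    for p in paths:
        with open(p) as fh:
            t, chrom = fh.readline().rstrip("\n").split("\t")
            file_marks = fh.readline().rstrip("\n").split("\t")
            arr = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
        if tissue is None:
            tissue, marks = t, file_marks
        elif t != tissue or file_marks != marks:
            raise ValueError("binary files disagree on tissue or mark ordering")
        data[chrom] = arr
    if tissue is None:
        raise ValueError("no binary files given")
    return BinaryMatrix(tissue=tissue, window_bp=window_bp, mark_names=marks, data=data)


# -- segmentation / model ---------------------------------------------------


def write_segmentation(seg: Segmentation, path) -> None:
    """BED of maximal constant-state runs, name = E<k+1> (1-based state ids)."""
    rows = []
    for chrom in sorted(seg.states):
        s = seg.states[chrom]
        if s.size == 0:
            continue
        change = np.flatnonzero(np.diff(s)) + 1
        bounds = np.concatenate([[0], change, [s.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(a) * seg.window_bp, int(b) * seg.window_bp, f"E{int(s[a]) + 1}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_segmentation(path, n_states: int, tissue: str = "", window_bp: int = 50) -> Segmentation:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    states: Dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        n_w = int(grp["end"].max()) // window_bp
        s = np.zeros(n_w, dtype=np.int64)
        for r in grp.itertuples():
            s[r.start // window_bp : r.end // window_bp] = int(str(r.name)[1:]) - 1
        states[str(chrom)] = s
    return Segmentation(tissue=tissue, n_states=n_states, window_bp=window_bp, states=states)


def write_model(results, json_path, text_path=None) -> None:
    Path(json_path).write_text(results.to_json())
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(results.summary() + "\n\nTransitions:\n")
            fh.write(
                pd.DataFrame(
                    results.transitions,
                    index=[f"E{k + 1}" for k in range(results.n_states)],
                    columns=[f"E{k + 1}" for k in range(results.n_states)],
                ).round(4).to_string()
                + "\n"
            )


def read_model(json_path):
    from .hmm import HMMResults

    return HMMResults.from_json(Path(json_path).read_text())


# -- config / json helpers --------------------------------------------------


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
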