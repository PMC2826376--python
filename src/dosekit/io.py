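"""Plain-text readers and writers (bedGraph, BED, TSV, YAML).

All genomic coordinates are 0-based half-open. Internally the pipeline
works on a 1 kb grid; files are written in base pairs (kb * 1000) so they
load cleanly in genome browsers and bedtools.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import CopySegmentMap, WindowTrack

KB = 1000


# -- windows ----------------------------------------------------------------

def write_windows_bedgraph(track: WindowTrack, path) -> None:
    """Window read counts as bedGraph (chrom, start, end, count)."""
    w = track.windows
    out = pd.DataFrame({"chrom": w["arm"], "start": w["start"] * KB,
                        "end": w["end"] * KB, "count": w["count"]})
    with open(path, "w") as fh:
        fh.write(f"# width_kb={track.width_kb} "
                 f"total_mapped_reads={track.total_mapped_reads}\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_windows_bedgraph(path, width_kb: int | None = None,
                          total_mapped_reads: int | None = None) -> WindowTrack:
    header = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            header = dict(kv.split("=") for kv in first[1:].split())
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, header=None,
                     names=["arm", "start", "end", "count"])
    df["start"] //= KB
    df["end"] //= KB
    width = width_kb or int(header.get("width_kb", 1))
    total = total_mapped_reads or (int(header["total_mapped_reads"])
                                   if "total_mapped_reads" in header else None)
    return WindowTrack(windows=df, width_kb=width, total_mapped_reads=total)


def write_windows_tsv(track: WindowTrack, path) -> None:
    track.windows.to_csv(path, sep="\t", index=False)


# -- genes ------------------------------------------------------------------

def write_genes_bed12(genes: pd.DataFrame, path) -> None:
    """Gene models as single-block BED12 records."""
    rows = []
    for _, g in genes.iterrows():
        s, e = int(g["start"]) * KB, int(g["end"]) * KB
        rows.append((g["arm"], s, e, g["gene_id"], 0, "+", s, e, "0",
                     1, e - s, 0))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    out = pd.DataFrame({"arm": df[0], "start": df[1] // KB,
                        "end": df[2] // KB, "gene_id": df[3]})
    return out[["gene_id", "arm", "start", "end"]]


# -- segments and breakpoints ----------------------------------------------

def write_segments(segmap: CopySegmentMap, out_dir) -> None:
    """Segments as BED (name=copy, score from confidence) plus full TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg = segmap.segments
    if segmap.has_copies:
        score = (seg["confidence"] == "confident").astype(int) * 1000
        name = seg["copy"].astype(str)
    else:
        score = 0
        name = "."
    bed = pd.DataFrame({"chrom": seg["arm"], "start": seg["start"] * KB,
                        "end": seg["end"] * KB, "name": name, "score": score})
    bed.to_csv(out_dir / "segments.bed", sep="\t", header=False, index=False)
    seg.to_csv(out_dir / "segments.tsv", sep="\t", index=False)
    segmap.breakpoints.assign(position=segmap.breakpoints["position"] * KB) \
        .to_csv(out_dir / "breakpoints.tsv", sep="\t", index=False)


# -- expression -------------------------------------------------------------

def write_expression_tsv(table: pd.DataFrame, path,
                         threshold: float | None = None,
                         alpha: float | None = None) -> None:
    with open(path, "w") as fh:
        if threshold is not None:
            fh.write(f"# expressed_threshold_rpkm={threshold:g} "
                     f"alpha={alpha if alpha is not None else ''}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        skip = 1 if fh.readline().startswith("#") else 0
    return pd.read_csv(path, sep="\t", skiprows=skip)


def read_yields_tsv(path) -> dict:
    """TSV of (condition, replicate, pg_per_cell) -> condition -> values."""
    df = pd.read_csv(path, sep="\t")
    return {cond: grp["pg_per_cell"].tolist()
            for cond, grp in df.groupby("condition", sort=False)}
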