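"""Readers and writers for the on-disk dialects.

BED/bedGraph/event tables are 0-based half-open; GTF is 1-based inclusive.
All writers emit deterministic, sorted text so identical runs byte-match.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ASEvent, CoverageTrack, Gene, GenomeAnnotation

EVENTS_COLUMNS = [
    "event_id",
    "type",
    "chrom",
    "strand",
    "alt_start",
    "alt_end",
    "up_exon_start",
    "up_exon_end",
    "down_exon_start",
    "down_exon_end",
    "gene_id",
]


# ---------------------------------------------------------------- annotation

def write_gtf(annotation: GenomeAnnotation, path: Path) -> None:
    lines = []
    for gene in annotation.genes:
        attrs = f'gene_id "{gene.gene_id}";'
        tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
        lines.append(
            _gtf_line(gene.chrom, "gene", gene.start, gene.end, gene.strand, attrs)
        )
        lines.append(
            _gtf_line(
                gene.chrom, "transcript", gene.start, gene.end, gene.strand, tattrs
            )
        )
        for start, end in gene.exons:
            lines.append(_gtf_line(gene.chrom, "exon", start, end, gene.strand, tattrs))
    Path(path).write_text("".join(lines))


def _gtf_line(chrom: str, feature: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    # convert half-open 0-based to GTF 1-based inclusive
    return f"{chrom}\tsplicemark\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def read_gtf(path: Path) -> GenomeAnnotation:
    genes: Dict[str, Gene] = {}
    maxpos: Dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, feature, start, end, _, strand, _, attrs = line.split("\t")
        start0, end0 = int(start) - 1, int(end)
        maxpos[chrom] = max(maxpos.get(chrom, 0), end0)
        gid = attrs.split('gene_id "', 1)[1].split('"', 1)[0]
        if feature == "gene":
            genes[gid] = Gene(gene_id=gid, chrom=chrom, strand=strand)
        elif feature == "exon":
            genes[gid].exons.append((start0, end0))
    for g in genes.values():
        g.exons.sort()
    return GenomeAnnotation(contigs=dict(maxpos), genes=list(genes.values()))


# -------------------------------------------------------------------- events

def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": e.event_id,
            "type": e.etype,
            "chrom": e.chrom,
            "strand": e.strand,
            "alt_start": e.alt_start,
            "alt_end": e.alt_end,
            "up_exon_start": e.upstream_exon[0],
            "up_exon_end": e.upstream_exon[1],
            "down_exon_start": e.downstream_exon[0],
            "down_exon_end": e.downstream_exon[1],
            "gene_id": e.gene_id,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events(events: Sequence[ASEvent], path: Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> List[ASEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ASEvent(
            event_id=r.event_id,
            etype=r.type,
            chrom=r.chrom,
            strand=r.strand,
            alt_start=int(r.alt_start),
            alt_end=int(r.alt_end),
            upstream_exon=(int(r.up_exon_start), int(r.up_exon_end)),
            downstream_exon=(int(r.down_exon_start), int(r.down_exon_end)),
            gene_id=r.gene_id,
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------------ coverage

def write_bedgraph(track: CoverageTrack, path: Path) -> None:
    """Run-length encoded bedGraph; zero runs are omitted (standard sparse form)."""
    with open(path, "w") as fh:
        fh.write(f"# celltype={track.celltype} library_size={track.library_size}\n")
        for chrom in sorted(track.counts):
            arr = track.counts[chrom]
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: Path, contigs: Dict[str, int], celltype: str | None = None) -> CoverageTrack:
    library_size = None
    rows: List[Tuple[str, int, int, int]] = []
    extent: Dict[str, int] = dict(contigs)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "library_size=" in line:
                    library_size = int(line.rsplit("library_size=", 1)[1])
                if celltype is None and "celltype=" in line:
                    celltype = line.split("celltype=", 1)[1].split()[0]
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), int(value)))
            extent[chrom] = max(extent.get(chrom, 0), int(end))
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in extent.items()}
    for chrom, start, end, value in rows:
        counts[chrom][start:end] = value
    total = int(sum(int(a.sum()) for a in counts.values()))
    return CoverageTrack(
        celltype=celltype or Path(path).stem,
        counts=counts,
        library_size=library_size if library_size is not None else total,
    )


def coverage_from_bam(path: Path, celltype: str) -> CoverageTrack:
    """Extract per-base read-start counts from a coordinate-sorted BAM."""
    import pysam  # optional dependency, text pipelines never need it

    counts: Dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for name, length in zip(bam.references, bam.lengths):
            counts[name] = np.zeros(length, dtype=np.int64)
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            counts[read.reference_name][pos] += 1
    total = int(sum(int(a.sum()) for a in counts.values()))
    return CoverageTrack(celltype=celltype, counts=counts, library_size=total)


# ----------------------------------------------------------------- BED peaks

def write_bed(intervals: Iterable[Tuple[str, int, int]], path: Path, name_prefix: str = "peak") -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(sorted(intervals)):
            fh.write(f"{chrom}\t{start}\t{end}\t{name_prefix}_{i + 1}\t0\t.\n")


def read_bed(path: Path) -> List[Tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# -------------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: Path):
    return json.loads(Path(path).read_text())
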