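"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory (BED convention);
GTF emission converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

EVENT_TYPES = ("SE", "MXE", "RI", "A5SS", "A3SS")

Interval = Tuple[int, int]  # (start, end), 0-based half-open


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event.

    ``upstream_exon`` / ``downstream_exon`` are in transcription
    orientation: on the minus strand the transcriptionally upstream exon is
    genomically to the right of the alternative element.
    """

    event_id: str
    etype: str
    chrom: str
    strand: str
    alt_start: int
    alt_end: int
    upstream_exon: Interval
    downstream_exon: Interval
    gene_id: str

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown AS event type {self.etype!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.alt_start < self.alt_end:
            raise ValueError(f"{self.event_id}: empty alternative element")
        left, right = (
            (self.upstream_exon, self.downstream_exon)
            if self.strand == "+"
            else (self.downstream_exon, self.upstream_exon)
        )
        if not (left[1] <= self.alt_start and self.alt_end <= right[0]):
            raise ValueError(
                f"{self.event_id}: alternative element must lie between its "
                f"flanking exons (genomic order)"
            )

    @property
    def left_exon(self) -> Interval:
        """Genomically left flanking exon."""
        return self.upstream_exon if self.strand == "+" else self.downstream_exon

    @property
    def right_exon(self) -> Interval:
        return self.downstream_exon if self.strand == "+" else self.upstream_exon

    @property
    def splicing_exon_start(self) -> int:
        """Transcription-orientation start of the alternative element.

        This is the anchor used by meta-profiles.
        """
        return self.alt_start if self.strand == "+" else self.alt_end


@dataclass(frozen=True)
class PsiEstimate:
    """Posterior summary of percent-spliced-in for one event in one cell type."""

    event_id: str
    celltype: str
    psi: float
    ci_low: float
    ci_high: float
    n_inclusion: int
    n_exclusion: int
    passed_filter: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.psi <= self.ci_high <= 1.0):
            raise ValueError(
                f"{self.event_id}/{self.celltype}: interval must bracket psi in [0,1]"
            )


@dataclass(frozen=True)
class EventCall:
    event_id: str
    celltype: str
    called: bool
    isoform_label: Optional[str]


@dataclass
class CoverageTrack:
    """Per-base read-start counts for one cell type.

    ``counts`` maps contig name to an integer array over the full contig.
    ``library_size`` is the total number of mapped reads and always equals
    the sum of all counts.
    """

    celltype: str
    counts: Dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        total = int(sum(int(a.sum()) for a in self.counts.values()))
        if total != self.library_size:
            raise ValueError(
                f"{self.celltype}: library_size {self.library_size} != "
                f"summed counts {total}"
            )
        for name, arr in self.counts.items():
            if np.any(arr < 0):
                raise ValueError(f"{self.celltype}/{name}: negative counts")

    def region_sum(self, chrom: str, start: int, end: int) -> int:
        arr = self.counts[chrom]
        start = max(start, 0)
        end = min(end, len(arr))
        if end <= start:
            return 0
        return int(arr[start:end].sum())


@dataclass(frozen=True)
class WindowSet:
    """The four 50-bp splice-site windows of one event.

    ``w_alt5``/``w_alt3`` sit on the 5'/3' ends of the alternative element,
    ``w_up3`` on the 3' end of the upstream exon and ``w_down5`` on the 5'
    end of the downstream exon, all in transcription orientation.
    """

    event_id: str
    chrom: str
    w_alt5: Interval
    w_alt3: Interval
    w_up3: Interval
    w_down5: Interval
    clipped: bool = False

    def windows(self) -> List[Tuple[str, Interval]]:
        return [
            ("alt5", self.w_alt5),
            ("alt3", self.w_alt3),
            ("up3", self.w_up3),
            ("down5", self.w_down5),
        ]


@dataclass
class EnrichmentRecord:
    event_id: str
    gene_id: str
    celltype: str
    reads_alt5: int
    reads_alt3: int
    reads_up3: int
    reads_down5: int
    enrichment_per_kb: float
    klass: Optional[str] = None  # {"higher", "same", "lower"}
    has_peak: bool = False

    @property
    def window_reads(self) -> int:
        return self.reads_alt5 + self.reads_alt3 + self.reads_up3 + self.reads_down5


@dataclass
class MetaProfile:
    """Positional mean of per-event z-scored coverage densities."""

    positions: np.ndarray  # offsets relative to the splicing exon start
    mean_z: np.ndarray
    n_events: int
    n_excluded_constant: int


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Interval] = field(default_factory=list)  # genomic order

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GenomeAnnotation:
    contigs: Dict[str, int]  # contig -> length
    genes: List[Gene]

    def genes_by_id(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


def iter_event_gene_ids(events: Iterable[ASEvent]) -> set:
    return {e.gene_id for e in events}
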