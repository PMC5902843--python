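"""H3K79me2 (or any coverage mark) enrichment around splice sites.

Quantifies read-start coverage in four 50-bp windows on the splice
boundaries of each alternative-splicing event, normalizes gene-level
enrichment per kb and per 10^7 mapped reads, classifies each site as
higher/same/lower than a randomized non-AS control rate with an exact
two-sided Poisson test, calls peaks with a sliding-window Poisson caller,
and builds z-scored positional meta-profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    ASEvent,
    CoverageTrack,
    EnrichmentRecord,
    GenomeAnnotation,
    Interval,
    MetaProfile,
    WindowSet,
)

#: half-width of each splice-site window ("50 bp around" = 25 bp each side)
DEFAULT_FLANK = 25
#: library-normalization scale: enrichment is reported per 10^7 mapped reads
LIBRARY_SCALE = 1e7


# ------------------------------------------------------------------- windows

def build_windows(event: ASEvent, flank: int = DEFAULT_FLANK, contig_length: Optional[int] = None) -> WindowSet:
    """Four ``2*flank``-bp windows centered on the event's splice boundaries.

    5'/3' are resolved in transcription orientation, so on the minus strand
    the alternative element's 5' end is its genomically right edge. Windows
    running past the contig are clipped and flagged.
    """
    if event.strand == "+":
        b_alt5, b_alt3 = event.alt_start, event.alt_end
        b_up3 = event.upstream_exon[1]
        b_down5 = event.downstream_exon[0]
    else:
        b_alt5, b_alt3 = event.alt_end, event.alt_start
        b_up3 = event.upstream_exon[0]
        b_down5 = event.downstream_exon[1]

    clipped = False

    def window(boundary: int) -> Interval:
        nonlocal clipped
        lo, hi = boundary - flank, boundary + flank
        if lo < 0:
            lo, clipped = 0, True
        if contig_length is not None and hi > contig_length:
            hi, clipped = contig_length, True
        return (lo, hi)

    return WindowSet(
        event_id=event.event_id,
        chrom=event.chrom,
        w_alt5=window(b_alt5),
        w_alt3=window(b_alt3),
        w_up3=window(b_up3),
        w_down5=window(b_down5),
        clipped=clipped,
    )


def window_read_counts(track: CoverageTrack, ws: WindowSet) -> Dict[str, int]:
    return {
        name: track.region_sum(ws.chrom, start, end)
        for name, (start, end) in ws.windows()
    }


# ------------------------------------------------------------- enrichment/kb

def enrichment_per_kb(
    track: CoverageTrack,
    regions: Sequence[Tuple[str, int, int]],
    library_scale: float = LIBRARY_SCALE,
) -> float:
    """Reads in ``regions`` per kb of region length per ``library_scale`` mapped reads.

    The canonical region set for a gene is its exons each padded by 50 bp.
    Overlapping regions are merged before counting so no base is double
    counted.
    """
    merged = merge_regions(regions)
    total_len = sum(end - start for _, start, end in merged)
    if total_len == 0:
        raise ValueError("zero-length region set")
    reads = sum(track.region_sum(chrom, start, end) for chrom, start, end in merged)
    if track.library_size == 0:
        return 0.0
    return reads / (total_len / 1000.0) / (track.library_size / library_scale)


def gene_region_set(gene, pad: int = 50) -> List[Tuple[str, int, int]]:
    """Exon part of a gene plus ``pad`` bp upstream/downstream of each exon."""
    return [(gene.chrom, max(0, s - pad), e + pad) for s, e in gene.exons]


def merge_regions(regions: Iterable[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    out: List[Tuple[str, int, int]] = []
    for chrom, start, end in sorted(regions):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return out


# ------------------------------------------------------------------ controls

@dataclass
class ControlSet:
    """Window sets sampled from internal exons of genes without any AS event."""

    windows: List[WindowSet]
    source_genes: List[str]
    seed: int


def sample_controls(
    annotation: GenomeAnnotation,
    events: Sequence[ASEvent],
    n: int,
    seed: int,
    flank: int = DEFAULT_FLANK,
) -> ControlSet:
    """Sample ``n`` non-AS window sets, without replacement, reproducibly.

    Each eligible site is an internal exon of an AS-free gene; its window
    geometry mirrors a skipped exon (exon boundaries = alternative element,
    neighboring exons = flanks).
    """
    as_genes = {e.gene_id for e in events}
    eligible: List[Tuple[str, int]] = []  # (gene_id, internal exon index)
    by_id = annotation.genes_by_id()
    for gene in annotation.genes:
        if gene.gene_id in as_genes:
            continue
        for i in range(1, len(gene.exons) - 1):
            eligible.append((gene.gene_id, i))
    if len(eligible) < n:
        raise ValueError(
            f"need {n} control exons but only {len(eligible)} internal exons "
            f"exist in AS-free genes (short by {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    windows, source = [], []
    for k, j in enumerate(sorted(idx.tolist())):
        gid, i = eligible[j]
        gene = by_id[gid]
        pseudo = ASEvent(
            event_id=f"ctrl_{k + 1}",
            etype="SE",
            chrom=gene.chrom,
            strand=gene.strand,
            alt_start=gene.exons[i][0],
            alt_end=gene.exons[i][1],
            upstream_exon=gene.exons[i - 1] if gene.strand == "+" else gene.exons[i + 1],
            downstream_exon=gene.exons[i + 1] if gene.strand == "+" else gene.exons[i - 1],
            gene_id=gid,
        )
        windows.append(build_windows(pseudo, flank=flank))
        source.append(gid)
    return ControlSet(windows=windows, source_genes=source, seed=seed)


def control_rate(track: CoverageTrack, controls: ControlSet) -> float:
    """Mean read-start rate (reads/bp) over all control windows."""
    reads = 0
    length = 0
    for ws in controls.windows:
        for _, (start, end) in ws.windows():
            reads += track.region_sum(ws.chrom, start, end)
            length += end - start
    if length == 0:
        raise ValueError("empty control set")
    return reads / length


# ------------------------------------------------------------ classification

def classify_site(
    site_reads: int,
    site_length: int,
    rate: float,
    lib_factor: float = 1.0,
    alpha: float = 0.05,
) -> str:
    """Exact two-sided Poisson test of a site count against a control rate.

    Expected count is ``rate * site_length * lib_factor``. Returns "higher"
    or "lower" when the two-sided p-value clears ``alpha``, else "same".
    """
    expected = rate * site_length * lib_factor
    if expected == 0:
        return "same" if site_reads == 0 else "higher"
    p = poisson_two_sided(site_reads, expected)
    if p < alpha:
        return "higher" if site_reads > expected else "lower"
    return "same"


def classify_sites(
    site_reads: np.ndarray,
    site_lengths: np.ndarray,
    rate: float,
    lib_factor: float = 1.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Vectorized :func:`classify_site` over arrays of sites."""
    x = np.asarray(site_reads, dtype=np.int64)
    expected = rate * np.asarray(site_lengths, dtype=float) * lib_factor
    p = np.minimum(
        1.0,
        2.0 * np.minimum(stats.poisson.cdf(x, expected), stats.poisson.sf(x - 1, expected)),
    )
    out = np.full(x.shape, "same", dtype=object)
    sig = (p < alpha) & (expected > 0)
    out[sig & (x > expected)] = "higher"
    out[sig & (x < expected)] = "lower"
    out[(expected == 0) & (x > 0)] = "higher"
    return out.astype(str)


def poisson_two_sided(x: int, mu: float) -> float:
    return min(1.0, 2.0 * min(stats.poisson.cdf(x, mu), stats.poisson.sf(x - 1, mu)))


def summarize_classes(classes: Sequence[str]) -> pd.DataFrame:
    """Counts and one-decimal percentages of higher/same/lower labels."""
    if len(classes) == 0:
        raise ValueError("no records to summarize")
    total = len(classes)
    rows = []
    for label in ("higher", "same", "lower"):
        count = sum(1 for c in classes if c == label)
        rows.append(
            {"class": label, "count": count, "percent": round(100.0 * count / total, 1)}
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- peaks

def call_peaks_simple(
    track: CoverageTrack,
    window: int = 200,
    step: int = 50,
    qmax: float = 0.01,
    local_bg_span: int = 10_000,
) -> List[Tuple[str, int, int]]:
    """Sliding-window Poisson peak caller.

    For each window the background rate is the larger of the track-wide
    mean and the mean over a ``local_bg_span`` neighborhood; window counts
    are tested against Poisson(background x window), p-values BH-adjusted
    across all windows, and significant windows (q < ``qmax``) are merged.
    """
    if qmax <= 0:
        return []
    candidates: List[Tuple[str, int, int]] = []
    pvals: List[float] = []
    for chrom in sorted(track.counts):
        arr = track.counts[chrom]
        n = len(arr)
        if n < window:
            continue
        csum = np.concatenate([[0], np.cumsum(arr)])
        starts = np.arange(0, n - window + 1, step)
        counts = csum[starts + window] - csum[starts]
        global_rate = arr.sum() / n
        half = local_bg_span // 2
        lo = np.maximum(starts + window // 2 - half, 0)
        hi = np.minimum(starts + window // 2 + half, n)
        local_rate = (csum[hi] - csum[lo]) / (hi - lo)
        lam = np.maximum(global_rate, local_rate) * window
        p = stats.poisson.sf(counts - 1, lam)
        for s, pv in zip(starts, p):
            candidates.append((chrom, int(s), int(s + window)))
            pvals.append(float(pv))
    if not candidates:
        return []
    reject, _, _, _ = multipletests(pvals, alpha=qmax, method="fdr_bh")
    significant = [iv for iv, r in zip(candidates, reject) if r]
    return merge_regions(significant)


def peak_overlap_fraction(
    window_sets: Sequence[WindowSet],
    peaks: Sequence[Tuple[str, int, int]],
) -> float:
    """Fraction of events with >=1 bp of peak overlap in any of the four windows."""
    if not window_sets:
        return 0.0
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in peaks:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    hit = 0
    for ws in window_sets:
        tree = trees.get(ws.chrom)
        if tree is None:
            continue
        if any(tree.overlap(start, end) for _, (start, end) in ws.windows()):
            hit += 1
    return hit / len(window_sets)


# -------------------------------------------------------------- meta-profile

def meta_profile(
    tracks: CoverageTrack | Sequence[CoverageTrack],
    events: Sequence[ASEvent],
    span: Tuple[int, int] = (-200, 400),
) -> MetaProfile:
    """Mean of per-event z-scored densities anchored at the splicing exon start.

    Minus-strand events are reflected before anchoring so position +x is
    always x bp downstream in transcription orientation. Events whose
    density is constant over the span (z-score undefined) are excluded and
    counted.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    lo, hi = span
    width = hi - lo
    acc = np.zeros(width)
    n_used = 0
    n_const = 0
    for track in tracks:
        for event in events:
            arr = track.counts[event.chrom]
            anchor = event.splicing_exon_start
            if event.strand == "+":
                start, end = anchor + lo, anchor + hi
                if start < 0 or end > len(arr):
                    continue
                vec = arr[start:end].astype(float)
            else:
                # reflect: genomic anchor-x is transcriptional +x
                start, end = anchor - hi, anchor - lo
                if start < 0 or end > len(arr):
                    continue
                vec = arr[start:end][::-1].astype(float)
            sd = vec.std()
            if sd == 0:
                n_const += 1
                continue
            acc += (vec - vec.mean()) / sd
            n_used += 1
    if n_used == 0:
        raise ValueError("no event with non-constant density in the span")
    return MetaProfile(
        positions=np.arange(lo, hi),
        mean_z=acc / n_used,
        n_events=n_used,
        n_excluded_constant=n_const,
    )


# ------------------------------------------------------ per-event enrichment

def enrich_events(
    tracks: Sequence[CoverageTrack],
    events: Sequence[ASEvent],
    annotation: GenomeAnnotation,
    controls: ControlSet,
    alpha: float = 0.05,
    flank: int = DEFAULT_FLANK,
    peaks_by_celltype: Optional[Dict[str, Sequence[Tuple[str, int, int]]]] = None,
) -> List[EnrichmentRecord]:
    """Full per-event x cell-type enrichment table.

    For each cell type: window read counts, gene-level enrichment/kb,
    higher/same/lower class versus that track's control rate, and peak
    overlap flags when peaks are supplied.
    """
    genes = annotation.genes_by_id()
    window_sets = {
        e.event_id: build_windows(e, flank=flank, contig_length=annotation.contigs[e.chrom])
        for e in events
    }
    gene_epk_cache: Dict[Tuple[str, str], float] = {}
    records: List[EnrichmentRecord] = []
    for track in tracks:
        rate = control_rate(track, controls)
        trees: Dict[str, IntervalTree] = {}
        if peaks_by_celltype and track.celltype in peaks_by_celltype:
            for chrom, s, e_ in peaks_by_celltype[track.celltype]:
                trees.setdefault(chrom, IntervalTree()).addi(s, e_)
        for event in events:
            ws = window_sets[event.event_id]
            counts = window_read_counts(track, ws)
            site_reads = sum(counts.values())
            site_len = sum(end - start for _, (start, end) in ws.windows())
            key = (event.gene_id, track.celltype)
            if key not in gene_epk_cache:
                gene_epk_cache[key] = enrichment_per_kb(
                    track, gene_region_set(genes[event.gene_id])
                )
            klass = classify_site(site_reads, site_len, rate, alpha=alpha)
            has_peak = False
            if trees:
                tree = trees.get(ws.chrom)
                has_peak = tree is not None and any(
                    tree.overlap(s, e_) for _, (s, e_) in ws.windows()
                )
            records.append(
                EnrichmentRecord(
                    event_id=event.event_id,
                    gene_id=event.gene_id,
                    celltype=track.celltype,
                    reads_alt5=counts["alt5"],
                    reads_alt3=counts["alt3"],
                    reads_up3=counts["up3"],
                    reads_down5=counts["down5"],
                    enrichment_per_kb=gene_epk_cache[key],
                    klass=klass,
                    has_peak=has_peak,
                )
            )
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "gene_id": r.gene_id,
                "celltype": r.celltype,
                "reads_alt5": r.reads_alt5,
                "reads_alt3": r.reads_alt3,
                "reads_up3": r.reads_up3,
                "reads_down5": r.reads_down5,
                "enrichment_per_kb": r.enrichment_per_kb,
                "class": r.klass,
                "has_peak": r.has_peak,
            }
            for r in records
        ]
    )
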