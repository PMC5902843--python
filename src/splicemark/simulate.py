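"""Synthetic data generator with known ground truth.

Emulates the statistical structure the pipeline consumes: five AS event
types with controllable true psi, binomial junction-read sampling, Poisson
background ChIP coverage with multiplicative enrichment bumps in the four
splice-site windows, cell types partitioned into planted enrichment
clusters, and null (or shifted) log-normal expression. Everything is a
pure function of the config including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io
from .enrichment import build_windows
from .types import ASEvent, CoverageTrack, EVENT_TYPES, Gene, GenomeAnnotation

CONTIG = "chrS1"
INTERGENE_GAP = 1000

DEFAULT_MIX = {"SE": 0.6, "MXE": 0.1, "RI": 0.1, "A5SS": 0.1, "A3SS": 0.1}


@dataclass
class SimConfig:
    """Study conditions for the synthetic run.

    Defaults are the desk-scale conditions the pipeline is exercised and
    tested at: 200 genes, 6 cell types split into two planted enrichment
    clusters, ~50 junction reads per event, 0.1 reads/bp ChIP background
    with a 4x enrichment bump at marked splice windows.
    """

    n_genes: int = 200
    exons_per_gene: Tuple[int, int] = (4, 8)
    exon_len: Tuple[int, int] = (80, 200)
    intron_len: Tuple[int, int] = (200, 500)
    n_celltypes: int = 6
    celltype_cluster_labels: Optional[List[int]] = None  # default: two halves
    event_type_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    true_psi_by_event: Optional[Dict[str, float]] = None
    depth: float = 50.0
    chip_background_rate: float = 0.1
    chip_effect_size: float = 4.0
    library_size: Optional[int] = None  # None = record the realized sum
    as_gene_fraction: float = 0.6
    expression_shift: float = 0.0  # SE-gene log-mean shift, in SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.event_type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_type_mix must sum to 1")
        if any(v < 0 for v in self.event_type_mix.values()):
            raise ValueError("event_type_mix proportions must be non-negative")
        if self.depth <= 0 or self.chip_background_rate <= 0:
            raise ValueError("rates must be positive")
        if self.chip_effect_size <= 0:
            raise ValueError("chip_effect_size must be positive")
        if not 0 < self.as_gene_fraction <= 1:
            raise ValueError("as_gene_fraction must be in (0, 1]")
        if self.intron_len[1] < 200:
            raise ValueError(
                "intron_len upper bound must allow introns >= 200 bp so the "
                "two 50-bp splice windows (plus A5SS/A3SS shifts) cannot collide"
            )
        if self.celltype_cluster_labels is None:
            half = self.n_celltypes // 2
            self.celltype_cluster_labels = [0] * half + [1] * (self.n_celltypes - half)
        if len(self.celltype_cluster_labels) != self.n_celltypes:
            raise ValueError("celltype_cluster_labels must cover every cell type")
        if self.true_psi_by_event is not None:
            for k, v in self.true_psi_by_event.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"psi for {k} outside [0,1]")

    @property
    def celltypes(self) -> List[str]:
        return [f"ct{i + 1:02d}" for i in range(self.n_celltypes)]


@dataclass
class GroundTruth:
    """Planted truth: per-event psi and cluster, per-cell-type cluster."""

    event_psi: Dict[str, float]
    event_cluster: Dict[str, int]  # which cell-type cluster is enriched here
    event_class: Dict[str, str]  # "higher" for marked events, else "same"
    celltype_cluster: Dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "event_psi": self.event_psi,
            "event_cluster": self.event_cluster,
            "event_class": self.event_class,
            "celltype_cluster": self.celltype_cluster,
        }


def derive_seed(master: int, *streams: int) -> int:
    """Stable per-stream sub-seed via splitmix64-style mixing (< 2^31)."""
    z = (master & 0xFFFFFFFFFFFFFFFF) or 0x9E3779B97F4A7C15
    for s in streams:
        z = (z + 0x9E3779B97F4A7C15 + s) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        z = z ^ (z >> 31)
    return int(z % (2**31))


# ---------------------------------------------------------------- annotation

def simulate_annotation(cfg: SimConfig) -> Tuple[GenomeAnnotation, List[ASEvent], GroundTruth]:
    """Tile non-overlapping genes on one contig and plant one AS event in a
    fraction of them.

    Introns are redrawn until they are long enough that two 50-bp windows on
    their flanking boundaries cannot collide. Strands alternate so both are
    represented. The returned ground truth carries true psi and the planted
    cell-type cluster for every event.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, 1))
    genes: List[Gene] = []
    events: List[ASEvent] = []
    event_psi: Dict[str, float] = {}
    event_cluster: Dict[str, int] = {}

    clusters = sorted(set(cfg.celltype_cluster_labels))
    n_as = int(round(cfg.n_genes * cfg.as_gene_fraction))
    as_flags = np.zeros(cfg.n_genes, dtype=bool)
    as_flags[rng.choice(cfg.n_genes, size=n_as, replace=False)] = True
    types = list(cfg.event_type_mix)
    probs = np.array([cfg.event_type_mix[t] for t in types])

    cursor = INTERGENE_GAP
    as_counter = 0
    for gi in range(cfg.n_genes):
        gid = f"g{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        # MXE needs four exons: two flanks around the mutually exclusive pair
        n_exons = max(n_exons, 4)
        exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, size=n_exons)
        intron_lens = []
        for _ in range(n_exons - 1):
            il = int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
            while il < 200:  # window collision guard (2 x 50 bp + A5SS/A3SS shift)
                il = int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
            intron_lens.append(il)
        exons = []
        pos = cursor
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos = exons[-1][1] + (intron_lens[k] if k < n_exons - 1 else 0)
        gene = Gene(gene_id=gid, chrom=CONTIG, strand=strand, exons=exons)
        genes.append(gene)
        cursor = gene.end + INTERGENE_GAP

        if not as_flags[gi]:
            continue
        as_counter += 1
        etype = types[int(rng.choice(len(types), p=probs))]
        eid = f"ev{as_counter:04d}_{etype}"
        event = _plant_event(eid, etype, gene, rng)
        events.append(event)
        # always consume the draw so overrides never perturb later geometry
        psi = _draw_psi(rng)
        if cfg.true_psi_by_event and eid in cfg.true_psi_by_event:
            psi = cfg.true_psi_by_event[eid]
        event_psi[eid] = float(psi)
        event_cluster[eid] = clusters[(as_counter - 1) % len(clusters)]

    contig_len = cursor + INTERGENE_GAP
    annotation = GenomeAnnotation(contigs={CONTIG: contig_len}, genes=genes)
    marked = cfg.chip_effect_size != 1.0
    truth = GroundTruth(
        event_psi=event_psi,
        event_cluster=event_cluster,
        event_class={e: ("higher" if marked else "same") for e in event_psi},
        celltype_cluster=dict(zip(cfg.celltypes, cfg.celltype_cluster_labels)),
    )
    return annotation, events, truth


def _draw_psi(rng: np.random.Generator) -> float:
    """Mixture favoring the extreme psi the isoform-calling thresholds target."""
    u = rng.random()
    if u < 0.45:
        return rng.uniform(0.0, 0.2)
    if u < 0.9:
        return rng.uniform(0.8, 1.0)
    return rng.uniform(0.2, 0.8)


def _plant_event(eid: str, etype: str, gene: Gene, rng: np.random.Generator) -> ASEvent:
    ex = gene.exons
    n = len(ex)
    plus = gene.strand == "+"
    if etype == "SE":
        j = int(rng.integers(1, n - 1))
        alt = ex[j]
        left, right = ex[j - 1], ex[j + 1]
    elif etype == "MXE":
        j = int(rng.integers(1, n - 2))
        # psi refers to the transcriptionally upstream of the two alternatives
        alt = ex[j] if plus else ex[j + 1]
        left, right = ex[j - 1], ex[j + 2]
    elif etype == "RI":
        j = int(rng.integers(0, n - 1))
        alt = (ex[j][1], ex[j + 1][0])
        left, right = ex[j], ex[j + 1]
    elif etype == "A5SS":
        j = int(rng.integers(0, n - 1))
        d = int(rng.integers(30, 81))
        if plus:  # extension of the upstream exon's 3' end
            alt = (ex[j][1], ex[j][1] + d)
        else:
            alt = (ex[j + 1][0] - d, ex[j + 1][0])
        left, right = ex[j], ex[j + 1]
    elif etype == "A3SS":
        j = int(rng.integers(0, n - 1))
        d = int(rng.integers(30, 81))
        if plus:  # extension of the downstream exon's 5' end
            alt = (ex[j + 1][0] - d, ex[j + 1][0])
        else:
            alt = (ex[j][1], ex[j][1] + d)
        left, right = ex[j], ex[j + 1]
    else:  # pragma: no cover
        raise ValueError(etype)
    upstream, downstream = (left, right) if plus else (right, left)
    return ASEvent(
        event_id=eid,
        etype=etype,
        chrom=gene.chrom,
        strand=gene.strand,
        alt_start=alt[0],
        alt_end=alt[1],
        upstream_exon=upstream,
        downstream_exon=downstream,
        gene_id=gene.gene_id,
    )


# ------------------------------------------------------------ junction reads

def simulate_junction_counts(
    events: Sequence[ASEvent], truth: GroundTruth, cfg: SimConfig
) -> pd.DataFrame:
    """Inclusion ~ Binomial(n, psi_true) with n ~ Poisson(depth), per cell type."""
    rows = []
    for ci, ct in enumerate(cfg.celltypes):
        rng = np.random.default_rng(derive_seed(cfg.seed, 2, ci))
        for event in events:
            psi = truth.event_psi[event.event_id]
            n = int(rng.poisson(cfg.depth))
            incl = int(rng.binomial(n, psi)) if n > 0 else 0
            rows.append(
                {
                    "event_id": event.event_id,
                    "celltype": ct,
                    "inclusion": incl,
                    "exclusion": n - incl,
                    "zero_depth": n == 0,
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- ChIP coverage

def simulate_coverage(
    events: Sequence[ASEvent],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    cfg: SimConfig,
) -> Tuple[List[CoverageTrack], List[Tuple[str, int, int]]]:
    """Poisson read-start coverage with planted window enrichment.

    Each cell type draws from its own sub-seed so adding a cell type never
    perturbs the others. For a cell type in planted cluster c, the Poisson
    rate is multiplied by ``chip_effect_size`` inside the four windows of
    every event whose gene was assigned to cluster c. Returns the tracks and
    the union of enriched windows as truth peaks.
    """
    contig_len = annotation.contigs[CONTIG]
    windows_by_cluster: Dict[int, List[Tuple[int, int]]] = {}
    for event in events:
        ws = build_windows(event, contig_length=contig_len)
        windows_by_cluster.setdefault(truth.event_cluster[event.event_id], []).extend(
            iv for _, iv in ws.windows()
        )
    tracks = []
    for ci, ct in enumerate(cfg.celltypes):
        rng = np.random.default_rng(derive_seed(cfg.seed, 3, ci))
        rate = np.full(contig_len, cfg.chip_background_rate)
        cluster = truth.celltype_cluster[ct]
        for start, end in windows_by_cluster.get(cluster, []):
            rate[start:end] = cfg.chip_background_rate * cfg.chip_effect_size
        if cfg.library_size is None:
            counts = rng.poisson(rate).astype(np.int64)
            lib = int(counts.sum())
        else:
            counts = rng.multinomial(cfg.library_size, rate / rate.sum()).astype(np.int64)
            lib = cfg.library_size
        tracks.append(CoverageTrack(celltype=ct, counts={CONTIG: counts}, library_size=lib))
    truth_peaks = sorted(
        {(CONTIG, s, e) for ivs in windows_by_cluster.values() for s, e in ivs}
    )
    return tracks, truth_peaks


# ---------------------------------------------------------------- expression

def simulate_expression(
    annotation: GenomeAnnotation,
    events: Sequence[ASEvent],
    cfg: SimConfig,
    shift: Optional[float] = None,
) -> pd.DataFrame:
    """Log-normal expression, identical for SE and non-SE genes by default.

    ``shift`` (SD units on the log scale, default ``cfg.expression_shift``)
    moves the SE-associated genes' log-mean for power experiments.
    """
    if shift is None:
        shift = cfg.expression_shift
    rng = np.random.default_rng(derive_seed(cfg.seed, 4))
    se_genes = {e.gene_id for e in events if e.etype == "SE"}
    sigma = 1.0
    rows = []
    for gene in annotation.genes:
        mu = 3.0 + (shift * sigma if gene.gene_id in se_genes else 0.0)
        vals = rng.lognormal(mean=mu, sigma=sigma, size=cfg.n_celltypes)
        for ct, v in zip(cfg.celltypes, vals):
            rows.append({"gene_id": gene.gene_id, "celltype": ct, "expression": float(v)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- driver

def simulate_all(cfg: SimConfig, outdir: Path) -> Dict[str, Path]:
    """Run every generator and write the on-disk dialects; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, events, truth = simulate_annotation(cfg)
    counts = simulate_junction_counts(events, truth, cfg)
    tracks, truth_peaks = simulate_coverage(events, annotation, truth, cfg)
    expr = simulate_expression(annotation, events, cfg)

    paths = {
        "annotation": outdir / "annotation.gtf",
        "events": outdir / "events.tsv",
        "junction_counts": outdir / "junction_counts.tsv",
        "expression": outdir / "expression.tsv",
        "truth_peaks": outdir / "truth_peaks.bed",
        "ground_truth": outdir / "ground_truth.json",
    }
    io.write_gtf(annotation, paths["annotation"])
    io.write_events(events, paths["events"])
    io.write_table(counts, paths["junction_counts"])
    io.write_table(expr, paths["expression"])
    io.write_bed(truth_peaks, paths["truth_peaks"], name_prefix="truth")
    io.write_json(truth.to_json_dict(), paths["ground_truth"])
    for track in tracks:
        p = outdir / f"coverage_{track.celltype}.bedGraph"
        io.write_bedgraph(track, p)
        paths[f"coverage_{track.celltype}"] = p
    return paths
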