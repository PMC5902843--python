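"""End-to-end orchestration: config, staged execution, manifest, validation.

Stages run in dependency order (simulate -> psi -> enrich -> som ->
downstream); each stage records input/output checksums in a run manifest
and is skipped on re-run when its config and outputs are unchanged. All
tabular outputs are deterministic functions of the config, so two runs
with the same config byte-match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import downstream as ds
from . import enrichment as en
from . import events as ev
from . import io
from . import som as sm
from .simulate import SimConfig, derive_seed, simulate_all
from .types import GenomeAnnotation

log = logging.getLogger("splicemark")

STAGES = ("simulate", "psi", "enrich", "som", "downstream")

DEFAULT_CONFIG: Dict[str, dict] = {
    "outdir": "splicemark_run",
    "seed": 7,
    "stages": list(STAGES),
    "simulate": {
        "n_genes": 200,
        "n_celltypes": 6,
        "depth": 50.0,
        "chip_background_rate": 0.1,
        "chip_effect_size": 4.0,
        "as_gene_fraction": 0.6,
        "expression_shift": 0.0,
    },
    "psi": {
        "prior_a": 1.0,
        "prior_b": 1.0,
        "level": 0.95,
        "max_ci_width": 0.3,
        "min_depth": 10,
    },
    "enrich": {
        "alpha": 0.05,
        "flank": 25,
        "qmax": 0.01,
        "n_controls": 100,
        "call_peaks": True,
    },
    "som": {
        "nx": 12,
        "ny": 8,
        "k": 6,
        "epochs": 100,
        "n_perm": 2000,
        "row_scaling": "unit-variance",
    },
    "downstream": {
        "motifs": True,
        "flank_len": 50,
        "planted_motif_frac": 0.4,
    },
}


@dataclass
class RunConfig:
    outdir: Path
    seed: int
    stages: List[str]
    simulate: dict
    psi: dict
    enrich: dict
    som: dict
    downstream: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
        for key, value in raw.items():
            if isinstance(value, dict):
                bad = set(value) - set(DEFAULT_CONFIG[key])
                if bad:
                    raise ValueError(f"unknown keys in [{key}]: {sorted(bad)}")
                merged[key].update(value)
            else:
                merged[key] = value
        bad_stages = set(merged["stages"]) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        return cls(
            outdir=Path(merged["outdir"]),
            seed=int(merged["seed"]),
            stages=[s for s in STAGES if s in merged["stages"]],
            simulate=merged["simulate"],
            psi=merged["psi"],
            enrich=merged["enrich"],
            som=merged["som"],
            downstream=merged["downstream"],
        )

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(self.outdir)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config_yaml() -> str:
    return yaml.safe_dump(DEFAULT_CONFIG, sort_keys=False)


# ------------------------------------------------------------------ manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Execute the configured stages; returns the run manifest dict."""
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = io.read_json(manifest_path) if manifest_path.exists() else {}
    chash = cfg.config_hash()
    manifest = {"config_hash": chash, "config": cfg.to_dict(), "stages": {}}

    stage_fns = {
        "simulate": _stage_simulate,
        "psi": _stage_psi,
        "enrich": _stage_enrich,
        "som": _stage_som,
        "downstream": _stage_downstream,
    }
    for stage in cfg.stages:
        prev = previous.get("stages", {}).get(stage)
        expected = prev.get("outputs", {}) if prev else {}
        up_to_date = (
            not force
            and previous.get("config_hash") == chash
            and bool(expected)
            and all(
                (outdir / name).exists() and _sha256(outdir / name) == digest
                for name, digest in expected.items()
            )
        )
        if up_to_date:
            log.info("stage=%s skipped (up to date)", stage)
            manifest["stages"][stage] = {**prev, "skipped": True}
            continue
        t0 = time.time()
        try:
            outputs = stage_fns[stage](cfg)
        except Exception as exc:  # halt with the failing stage named
            raise StageError(stage, exc) from exc
        entry = {
            "outputs": {name: _sha256(outdir / name) for name in sorted(outputs)},
            "elapsed_s": round(time.time() - t0, 3),
            "skipped": False,
        }
        manifest["stages"][stage] = entry
        log.info("stage=%s outputs=%d elapsed=%.2fs", stage, len(outputs), entry["elapsed_s"])
        io.write_json(manifest, manifest_path)
    io.write_json(manifest, manifest_path)
    return manifest


# -------------------------------------------------------------------- stages

def _sim_config(cfg: RunConfig) -> SimConfig:
    return SimConfig(seed=cfg.seed, **cfg.simulate)


def _stage_simulate(cfg: RunConfig) -> List[str]:
    paths = simulate_all(_sim_config(cfg), cfg.outdir)
    return [p.name for p in paths.values()]


def _stage_psi(cfg: RunConfig) -> List[str]:
    events = io.read_events(cfg.outdir / "events.tsv")
    counts = io.read_table(cfg.outdir / "junction_counts.tsv")
    table = ev.estimate_psi_table(counts, events, **cfg.psi)
    io.write_table(table, cfg.outdir / "psi_calls.tsv")
    type_counts = ev.count_events_by_type(table)
    type_counts.reset_index().to_csv(cfg.outdir / "type_counts.tsv", sep="\t", index=False)
    return ["psi_calls.tsv", "type_counts.tsv"]


def _load_tracks(cfg: RunConfig, annotation: GenomeAnnotation):
    simcfg = _sim_config(cfg)
    return [
        io.read_bedgraph(cfg.outdir / f"coverage_{ct}.bedGraph", annotation.contigs, ct)
        for ct in simcfg.celltypes
    ]


def _stage_enrich(cfg: RunConfig) -> List[str]:
    annotation = io.read_gtf(cfg.outdir / "annotation.gtf")
    events = io.read_events(cfg.outdir / "events.tsv")
    tracks = _load_tracks(cfg, annotation)
    e = cfg.enrich
    controls = en.sample_controls(
        annotation, events, n=int(e["n_controls"]), seed=derive_seed(cfg.seed, 10),
        flank=int(e["flank"]),
    )
    outputs: List[str] = []
    peaks_by_ct = None
    if e["call_peaks"]:
        peaks_by_ct = {}
        for track in tracks:
            peaks = en.call_peaks_simple(track, qmax=float(e["qmax"]))
            name = f"peaks_{track.celltype}.bed"
            io.write_bed(peaks, cfg.outdir / name)
            outputs.append(name)
            peaks_by_ct[track.celltype] = peaks
    records = en.enrich_events(
        tracks, events, annotation, controls,
        alpha=float(e["alpha"]), flank=int(e["flank"]), peaks_by_celltype=peaks_by_ct,
    )
    rec_df = en.records_to_frame(records)
    etypes = {ev_.event_id: ev_.etype for ev_ in events}
    rec_df.insert(1, "type", rec_df["event_id"].map(etypes))
    io.write_table(rec_df, cfg.outdir / "enrichment.tsv")
    outputs.append("enrichment.tsv")

    summary_rows = []
    for etype, grp in rec_df.groupby("type"):
        s = en.summarize_classes(list(grp["class"]))
        s.insert(0, "type", etype)
        s["peak_overlap_percent"] = round(100.0 * grp["has_peak"].mean(), 1)
        summary_rows.append(s)
    io.write_table(pd.concat(summary_rows, ignore_index=True), cfg.outdir / "class_summary.tsv")
    outputs.append("class_summary.tsv")

    # per-cell-type control window enrichment (reads/bp) for cluster stats
    ctrl_rows = []
    for track in tracks:
        for ws in controls.windows:
            reads = sum(track.region_sum(ws.chrom, s, t) for _, (s, t) in ws.windows())
            length = sum(t - s for _, (s, t) in ws.windows())
            ctrl_rows.append(
                {
                    "control_id": ws.event_id,
                    "celltype": track.celltype,
                    "reads": reads,
                    "length": length,
                    "rate": reads / length,
                }
            )
    io.write_table(pd.DataFrame(ctrl_rows), cfg.outdir / "control_enrichment.tsv")
    outputs.append("control_enrichment.tsv")

    se_events = [x for x in events if x.etype == "SE"]
    if se_events:
        profile = en.meta_profile(tracks, se_events)
        io.write_table(
            pd.DataFrame({"position": profile.positions, "mean_z": profile.mean_z}),
            cfg.outdir / "meta_profile.tsv",
        )
        outputs.append("meta_profile.tsv")
    return outputs


def _stage_som(cfg: RunConfig) -> List[str]:
    rec = io.read_table(cfg.outdir / "enrichment.tsv")
    matrix = sm.build_gene_matrix(rec, etype="SE")
    s = cfg.som
    som_cfg = sm.SOMConfig(
        nx=int(s["nx"]), ny=int(s["ny"]), epochs=int(s["epochs"]),
        row_scaling=s["row_scaling"],
    )
    model = sm.train_som(matrix, som_cfg, seed=derive_seed(cfg.seed, 20))
    node_labels, homogeneity = sm.group_nodes(model, k=int(s["k"]))
    assignment = sm.assign_celltypes(matrix, model, node_labels)

    codebook = pd.DataFrame(model.codebook, columns=list(matrix.columns))
    codebook.insert(0, "node", np.arange(model.config.n_nodes))
    io.write_table(codebook, cfg.outdir / "som_codebook.tsv")
    io.write_table(homogeneity, cfg.outdir / "som_homogeneity.tsv")
    io.write_table(
        pd.DataFrame(
            {"node": np.arange(len(node_labels)), "cluster": node_labels}
        ),
        cfg.outdir / "som_nodes.tsv",
    )
    io.write_table(
        pd.DataFrame(
            sorted(assignment.celltype_cluster.items()),
            columns=["celltype", "cluster"],
        ),
        cfg.outdir / "celltype_clusters.tsv",
    )

    # per-cluster SE vs non-SE (control) enrichment statistics
    rec_se = rec[rec["type"] == "SE"].copy()
    win_len = 4 * 2 * int(cfg.enrich["flank"])
    rec_se["rate"] = (
        rec_se[["reads_alt5", "reads_alt3", "reads_up3", "reads_down5"]].sum(axis=1)
        / win_len
    )
    ctrl = io.read_table(cfg.outdir / "control_enrichment.tsv")
    stats_rows = []
    for cluster in sorted(set(assignment.celltype_cluster.values())):
        members = [ct for ct, c in assignment.celltype_cluster.items() if c == cluster]
        se_vals = rec_se[rec_se["celltype"].isin(members)]["rate"].to_numpy()
        ctrl_vals = ctrl[ctrl["celltype"].isin(members)]["rate"].to_numpy()
        if len(se_vals) == 0 or len(ctrl_vals) == 0:
            continue
        cs = sm.cluster_se_stats(
            cluster, se_vals, ctrl_vals, n_perm=int(s["n_perm"]),
            seed=derive_seed(cfg.seed, 21, cluster),
        )
        stats_rows.append(
            {
                "cluster": cs.cluster,
                "n_celltypes": len(members),
                "log2_fold_change": round(cs.log2_fold_change, 4),
                "p_value": cs.p_value,
                "p_label": cs.p_label,
            }
        )
    io.write_table(pd.DataFrame(stats_rows), cfg.outdir / "cluster_stats.tsv")
    return [
        "som_codebook.tsv",
        "som_homogeneity.tsv",
        "som_nodes.tsv",
        "celltype_clusters.tsv",
        "cluster_stats.tsv",
    ]


TOY_MOTIFS = [
    ds.PWM("toySF1", np.array([[0.97, 0.01, 0.01, 0.01]] * 6)),
    ds.PWM(
        "toySF2",
        np.array(
            [
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.97, 0.01, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.97, 0.01, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.97, 0.01, 0.01],
            ]
        ),
    ),
]
_MOTIF_CONSENSUS = {"toySF1": "AAAAAA", "toySF2": "GCGCGC"}


def synthetic_flanks(
    n_skip: int, n_control: int, flank_len: int, planted_frac: float, seed: int
) -> Dict[str, List[str]]:
    """Random flank sequences with a motif planted in a fraction of skip flanks.

    Synthetic stand-in for real splice-site flanks (the simulator is not
    sequence-level); exercises the scanning + enrichment path end to end.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand_seq() -> str:
        return "".join(rng.choice(bases, size=flank_len))

    skip = []
    for i in range(n_skip):
        seq = rand_seq()
        if rng.random() < planted_frac:
            motif = _MOTIF_CONSENSUS["toySF1" if i % 2 == 0 else "toySF2"]
            pos = int(rng.integers(0, flank_len - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        skip.append(seq)
    control = [rand_seq() for _ in range(n_control)]
    return {"skip": skip, "control": control}


def _stage_downstream(cfg: RunConfig) -> List[str]:
    events = io.read_events(cfg.outdir / "events.tsv")
    expr = io.read_table(cfg.outdir / "expression.tsv")
    as_genes = {x.gene_id for x in events}
    se_genes = sorted({x.gene_id for x in events if x.etype == "SE"})
    pool = sorted(set(expr["gene_id"]) - as_genes)
    comparison = ds.compare_expression(
        se_genes, pool, expr, seed=derive_seed(cfg.seed, 30)
    )
    io.write_json(
        {
            "statistic": comparison.statistic,
            "p_value": comparison.p_value,
            "median_log2_se": comparison.median_se,
            "median_log2_non_se": comparison.median_non_se,
            "n_se": comparison.n_se,
            "n_non_se": comparison.n_non_se,
        },
        cfg.outdir / "expression_comparison.json",
    )
    (cfg.outdir / "se_gene_list.txt").write_text("".join(g + "\n" for g in se_genes))
    outputs = ["expression_comparison.json", "se_gene_list.txt"]

    d = cfg.downstream
    if d["motifs"]:
        seqs = synthetic_flanks(
            n_skip=len(se_genes) or 50,
            n_control=len(pool) or 50,
            flank_len=int(d["flank_len"]) * 2,
            planted_frac=float(d["planted_motif_frac"]),
            seed=derive_seed(cfg.seed, 31),
        )
        scan = ds.scan_motifs(seqs, TOY_MOTIFS)
        hits = scan.hits.set_index(["motif_id", "window_class"])
        skip_hits = {
            m: (int(hits.loc[(m, "skip"), "n_hit"]), int(hits.loc[(m, "skip"), "n_sequences"]))
            for m in _MOTIF_CONSENSUS
        }
        ctrl_hits = {
            m: (
                int(hits.loc[(m, "control"), "n_hit"]),
                int(hits.loc[(m, "control"), "n_sequences"]),
            )
            for m in _MOTIF_CONSENSUS
        }
        io.write_table(ds.motif_enrichment(skip_hits, ctrl_hits), cfg.outdir / "motif_enrichment.tsv")
        outputs.append("motif_enrichment.tsv")
    return outputs


# ---------------------------------------------------------------- validation

def validate_inputs(paths: Dict[str, Path]) -> List[Dict[str, object]]:
    """Format validation; returns a list of violations (file, line, message).

    Known kinds: events, bed, bedgraph, gtf, junction_counts.
    """
    report: List[Dict[str, object]] = []

    def fail(path, line_no, message):
        report.append({"file": str(path), "line": line_no, "message": message})

    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            fail(path, 0, "file does not exist")
            continue
        if kind == "bed":
            for i, line in enumerate(path.read_text().splitlines(), 1):
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    fail(path, i, "fewer than 3 BED fields")
                    continue
                try:
                    s, e = int(f[1]), int(f[2])
                except ValueError:
                    fail(path, i, "non-integer coordinates")
                    continue
                if s >= e:
                    fail(path, i, f"start {s} >= end {e}")
                if s < 0:
                    fail(path, i, "negative start")
        elif kind == "bedgraph":
            last = {}
            for i, line in enumerate(path.read_text().splitlines(), 1):
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) != 4:
                    fail(path, i, "bedGraph needs 4 fields")
                    continue
                chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                if s >= e:
                    fail(path, i, f"start {s} >= end {e}")
                if v < 0:
                    fail(path, i, "negative coverage value")
                if chrom in last and s < last[chrom]:
                    fail(path, i, "intervals not sorted / overlap previous")
                last[chrom] = e
        elif kind == "gtf":
            gene_spans: Dict[str, tuple] = {}
            exon_lines: List[tuple] = []
            for i, line in enumerate(path.read_text().splitlines(), 1):
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 9:
                    fail(path, i, "GTF needs 9 fields")
                    continue
                start, end = int(f[3]), int(f[4])
                if start > end:
                    fail(path, i, f"start {start} > end {end}")
                gid = f[8].split('gene_id "', 1)[1].split('"', 1)[0] if 'gene_id "' in f[8] else None
                if gid is None:
                    fail(path, i, "missing gene_id attribute")
                    continue
                if f[2] == "gene":
                    gene_spans[gid] = (start, end)
                elif f[2] == "exon":
                    exon_lines.append((i, gid, start, end))
            for i, gid, start, end in exon_lines:
                span = gene_spans.get(gid)
                if span and not (span[0] <= start and end <= span[1]):
                    fail(path, i, f"exon outside gene {gid} span")
        elif kind == "events":
            df = pd.read_csv(path, sep="\t")
            for i, r in enumerate(df.itertuples(), 2):  # header = line 1
                if r.alt_start >= r.alt_end:
                    fail(path, i, "alt_start >= alt_end")
                if r.strand not in "+-":
                    fail(path, i, f"bad strand {r.strand!r}")
        elif kind == "junction_counts":
            df = pd.read_csv(path, sep="\t")
            for i, r in enumerate(df.itertuples(), 2):
                if r.inclusion < 0 or r.exclusion < 0:
                    fail(path, i, "negative junction counts")
                if int(r.inclusion) != r.inclusion or int(r.exclusion) != r.exclusion:
                    fail(path, i, "non-integer junction counts")
        else:
            fail(path, 0, f"unknown input kind {kind!r}")
    return report
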