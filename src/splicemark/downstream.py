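"""Downstream comparisons: expression of SE vs non-SE genes and
splicing-factor motif enrichment in splice-site flank sequences.

Expression is compared on log2(x+1) with a two-sided Mann-Whitney U test.
Motifs are scanned as plain log-odds position weight matrices (bits against
a background base composition) with a hit threshold at a fraction of the
maximum attainable score; per-motif enrichment of skip-site flanks versus
control flanks is a Fisher exact test with BH correction across motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

BASES = "ACGT"
UNIFORM_BG = {b: 0.25 for b in BASES}
DEFAULT_THRESHOLD_FRAC = 0.8


# ------------------------------------------------------------- expression

@dataclass
class ExpressionComparison:
    statistic: float
    p_value: float
    median_se: float
    median_non_se: float
    n_se: int
    n_non_se: int
    sampled_non_se: List[str]


def compare_expression(
    se_genes: Sequence[str],
    non_se_pool: Sequence[str],
    table: pd.DataFrame,
    seed: int = 0,
    n_control: Optional[int] = None,
) -> ExpressionComparison:
    """Mann-Whitney comparison of log2(expression+1) between gene groups.

    The non-SE control group is sampled from ``non_se_pool`` without
    replacement (default: same size as the SE group). ``table`` needs
    columns gene_id and expression; multiple cell types per gene are pooled.
    """
    se_set, pool_set = set(se_genes), set(non_se_pool)
    if se_set & pool_set:
        raise ValueError("SE and non-SE gene groups overlap")
    if len(se_set) < 10 or len(pool_set) < 10:
        raise ValueError("need at least 10 genes per group")
    rng = np.random.default_rng(seed)
    n_control = min(n_control or len(se_set), len(pool_set))
    pool_sorted = sorted(pool_set)
    picked = [pool_sorted[i] for i in rng.choice(len(pool_sorted), size=n_control, replace=False)]
    x = np.log2(table[table["gene_id"].isin(se_set)]["expression"].to_numpy() + 1.0)
    y = np.log2(table[table["gene_id"].isin(picked)]["expression"].to_numpy() + 1.0)
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return ExpressionComparison(
        statistic=float(stat),
        p_value=float(p),
        median_se=float(np.median(x)),
        median_non_se=float(np.median(y)),
        n_se=len(x),
        n_non_se=len(y),
        sampled_non_se=sorted(picked),
    )


# -------------------------------------------------------------------- PWMs

@dataclass
class PWM:
    """Position weight matrix of base probabilities (rows = positions)."""

    motif_id: str
    matrix: np.ndarray  # (L, 4) probabilities in ACGT order
    background: Dict[str, float] = field(default_factory=lambda: dict(UNIFORM_BG))
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must span at least 4 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudo: float = 1e-9) -> np.ndarray:
        bg = np.array([self.background[b] for b in BASES])
        return np.log2((self.matrix + pseudo) / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_frac * self.max_score


def read_meme(path) -> List[PWM]:
    """Load PWMs from MEME minimal text.

    Parsed directly (not via Bio.motifs, which round-trips probabilities
    through integer counts and quantizes them).
    """
    lines = [ln.strip() for ln in open(path)]
    background = dict(UNIFORM_BG)
    out: List[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                rows.append([float(v) for v in lines[i + 1 + j].split()])
            out.append(
                PWM(
                    motif_id=name,
                    matrix=np.asarray(rows),
                    background={b: background.get(b, 0.25) for b in BASES},
                )
            )
            i += 1 + width
            continue
        i += 1
    return out


# --------------------------------------------------------------- scanning

@dataclass
class ScanResult:
    hits: pd.DataFrame  # columns: motif_id, window_class, n_sequences, n_hit
    n_skipped_short: int


def score_offsets(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score at every offset of ``seq``; N contributes 0 at its position."""
    lods = pwm.log_odds()
    L = pwm.length
    n = len(seq) - L + 1
    if n <= 0:
        return np.zeros(0)
    idx = {b: i for i, b in enumerate(BASES)}
    scores = np.zeros(n)
    for off in range(n):
        s = 0.0
        for k in range(L):
            base = seq[off + k]
            if base in idx:
                s += lods[k, idx[base]]
        scores[off] = s
    return scores


def scan_motifs(
    sequences: Mapping[str, Sequence[str]],
    pwms: Sequence[PWM],
) -> ScanResult:
    """Count, per motif and window class, the sequences with >=1 hit.

    ``sequences`` maps a window class (e.g. "alt5", "control") to its flank
    sequences, uppercase over {A,C,G,T,N}. Minus-strand flanks are expected
    to be reverse-complemented upstream, so scanning is strand-agnostic.
    Sequences shorter than a motif are skipped and counted.
    """
    rows = []
    skipped = 0
    for pwm in pwms:
        thr = pwm.threshold
        for wclass, seqs in sequences.items():
            n_hit = 0
            n_used = 0
            for seq in seqs:
                seq = seq.upper()
                if len(seq) < pwm.length:
                    skipped += 1
                    continue
                n_used += 1
                if np.any(score_offsets(seq, pwm) >= thr):
                    n_hit += 1
            rows.append(
                {
                    "motif_id": pwm.motif_id,
                    "window_class": wclass,
                    "n_sequences": n_used,
                    "n_hit": n_hit,
                }
            )
    return ScanResult(hits=pd.DataFrame(rows), n_skipped_short=skipped)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(comp)[::-1]


# ------------------------------------------------------------- enrichment

def motif_enrichment(
    skip_hits: Mapping[str, Tuple[int, int]],
    control_hits: Mapping[str, Tuple[int, int]],
) -> pd.DataFrame:
    """Per-motif Fisher exact enrichment of skip-site hits over controls.

    Both mappings give motif_id -> (n_hit, n_total). Zero-margin tables get
    a Haldane 0.5 correction for the odds ratio (flagged); p-values are BH
    corrected across motifs and the table is ranked by (q, -OR).
    """
    rows = []
    for motif_id in sorted(skip_hits):
        a, na = skip_hits[motif_id]
        b, nb = control_hits[motif_id]
        table = np.array([[a, na - a], [b, nb - b]])
        if np.any(table < 0):
            raise ValueError(f"{motif_id}: hits exceed totals")
        _, p = stats.fisher_exact(table, alternative="two-sided")
        corrected = False
        t = table.astype(float)
        if 0 in t.sum(axis=0) or 0 in t.sum(axis=1) or 0 in t:
            t = t + 0.5
            corrected = True
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        rows.append(
            {
                "motif_id": motif_id,
                "skip_hit": a,
                "skip_total": na,
                "control_hit": b,
                "control_total": nb,
                "odds_ratio": float(odds),
                "p_value": float(p),
                "haldane_corrected": corrected,
            }
        )
    df = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = qvals
    return df.sort_values(["q_value", "odds_ratio"], ascending=[True, False]).reset_index(
        drop=True
    )
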