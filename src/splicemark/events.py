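"""Percent-spliced-in (psi) estimation and predominant-isoform calling.

psi for an event is the fraction of transcripts that include the
alternative element, estimated from inclusion vs exclusion junction reads
under a Beta-binomial model: with a Beta(a, b) prior the posterior after I
inclusion and S exclusion reads is Beta(a+I, b+S); the point estimate is
its mean and the interval its central posterior interval. Calls use the
type-specific thresholds: psi <= 0.2 for SE and A3SS, psi >= 0.8 for RI
and A5SS, and either tail for MXE.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .types import ASEvent, EventCall, PsiEstimate

PSI_CUTOFF_LOW = 0.2
PSI_CUTOFF_HIGH = 0.8
#: types whose predominant isoform excludes the alternative element
LOW_TAIL_TYPES = ("SE", "A3SS")
HIGH_TAIL_TYPES = ("RI", "A5SS")

DEFAULT_MAX_CI_WIDTH = 0.3
DEFAULT_MIN_DEPTH = 10

#: isoform label per (type, tail)
_LABELS = {
    ("SE", "low"): "skipped",
    ("A3SS", "low"): "excluded",
    ("RI", "high"): "retained",
    ("A5SS", "high"): "included",
    ("MXE", "low"): "downstream_exon",
    ("MXE", "high"): "upstream_exon",
}


def estimate_psi(
    inclusion: int,
    exclusion: int,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
    level: float = 0.95,
    max_ci_width: float = DEFAULT_MAX_CI_WIDTH,
    min_depth: int = DEFAULT_MIN_DEPTH,
    event_id: str = "",
    celltype: str = "",
) -> PsiEstimate:
    """Beta posterior summary of psi from junction read counts.

    Zero total depth returns the prior mean with ``passed_filter=False``;
    otherwise the filter requires interval width <= ``max_ci_width`` and
    depth >= ``min_depth``.
    """
    if inclusion < 0 or exclusion < 0:
        raise ValueError("read counts must be non-negative")
    a = prior_a + inclusion
    b = prior_b + exclusion
    psi = a / (a + b)
    tail = (1.0 - level) / 2.0
    ci_low = float(stats.beta.ppf(tail, a, b))
    ci_high = float(stats.beta.ppf(1.0 - tail, a, b))
    depth = inclusion + exclusion
    passed = depth > 0 and depth >= min_depth and (ci_high - ci_low) <= max_ci_width
    return PsiEstimate(
        event_id=event_id,
        celltype=celltype,
        psi=float(psi),
        ci_low=ci_low,
        ci_high=ci_high,
        n_inclusion=inclusion,
        n_exclusion=exclusion,
        passed_filter=passed,
    )


def call_predominant_isoform(
    est: PsiEstimate,
    etype: str,
    cutoff_low: float = PSI_CUTOFF_LOW,
    cutoff_high: float = PSI_CUTOFF_HIGH,
) -> EventCall:
    """Threshold a filtered psi estimate into a predominant-isoform call."""
    if not est.passed_filter:
        raise ValueError(
            f"{est.event_id}/{est.celltype}: refusing to call an unfiltered estimate"
        )
    called, label = False, None
    if etype in LOW_TAIL_TYPES:
        if est.psi <= cutoff_low:
            called, label = True, _LABELS[(etype, "low")]
    elif etype in HIGH_TAIL_TYPES:
        if est.psi >= cutoff_high:
            called, label = True, _LABELS[(etype, "high")]
    elif etype == "MXE":
        if est.psi <= cutoff_low:
            called, label = True, _LABELS[("MXE", "low")]
        elif est.psi >= cutoff_high:
            called, label = True, _LABELS[("MXE", "high")]
    else:
        raise ValueError(f"unknown AS event type {etype!r}")
    return EventCall(est.event_id, est.celltype, called, label)


def estimate_psi_table(
    counts: pd.DataFrame,
    events: Sequence[ASEvent],
    **kwargs,
) -> pd.DataFrame:
    """psi estimates + calls for every (event, cell type) row of a count table."""
    etypes = {e.event_id: e.etype for e in events}
    rows = []
    for r in counts.itertuples():
        est = estimate_psi(
            int(r.inclusion),
            int(r.exclusion),
            event_id=r.event_id,
            celltype=r.celltype,
            **kwargs,
        )
        call = (
            call_predominant_isoform(est, etypes[r.event_id])
            if est.passed_filter
            else EventCall(r.event_id, r.celltype, False, None)
        )
        rows.append(
            {
                "event_id": est.event_id,
                "celltype": est.celltype,
                "type": etypes[r.event_id],
                "psi": est.psi,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_inclusion": est.n_inclusion,
                "n_exclusion": est.n_exclusion,
                "passed_filter": est.passed_filter,
                "called": call.called,
                "isoform_label": call.isoform_label,
            }
        )
    return pd.DataFrame(rows)


def count_events_by_type(
    calls: pd.DataFrame, celltypes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-type x per-cell-type counts of called events, with a totals row.

    ``calls`` needs columns type, celltype, called.
    """
    if celltypes is None:
        celltypes = sorted(calls["celltype"].unique())
    table = pd.DataFrame(0, index=list(EVENT_ORDER), columns=list(celltypes))
    called = calls[calls["called"]]
    for (etype, ct), group in called.groupby(["type", "celltype"]):
        if etype in table.index and ct in table.columns:
            table.loc[etype, ct] = len(group)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "type"
    return table


EVENT_ORDER = ("SE", "MXE", "RI", "A5SS", "A3SS")


def cluster_event_profiles(
    matrix: pd.DataFrame,
) -> Tuple[np.ndarray, List[str]]:
    """Hierarchically cluster cell types by their event-count profiles.

    ``matrix`` holds features (e.g. per-type counts) in rows and cell types
    in columns. Features are standardized across cell types, then columns
    are clustered with complete linkage on Euclidean distance. Returns the
    linkage matrix and the leaf-ordered column names. Fully deterministic;
    scipy breaks ties by original index order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cell types to cluster")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    mean = X.mean(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    link = hierarchy.linkage(Z.T, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return link, [matrix.columns[i] for i in order]


def cut_tree(link: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels (1..k) from a linkage matrix."""
    return hierarchy.fcluster(link, t=k, criterion="maxclust")
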