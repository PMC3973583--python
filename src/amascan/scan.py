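"""Binomial coincidence scan for genomic clusters of top differentially
expressed genes.

Chromosome arms are tiled with overlapping bins (default 500 kb wide, every
250 kb).  With the top fraction q of genes flagged as most differentially
expressed, the number of flagged genes among the n_b genes resident in a bin
follows Binomial(n_b, q) under the null of no positional clustering.  Each
bin is scored as log10 of the inverse upper-tail probability, so a score of
2 means a bin this enriched arises at most 1 in 100 times by chance — the
default calling cutoff.  Runs of above-cutoff bins merge into cluster calls.

Genes are assigned to bins by their midpoint, so per-bin counts do not depend
on gene length and, with width = 2 x step, every interior gene is counted in
exactly two bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneCatalog
from .stats import binomial_tail

__all__ = [
    "make_bins",
    "select_top_fraction",
    "score_bins",
    "call_clusters",
    "ClusterCall",
    "binomial_tail",
]

DEFAULT_WIDTH = 500_000
DEFAULT_STEP = 250_000
DEFAULT_FRACTION = 0.01
DEFAULT_CUTOFF = 2.0


@dataclass
class ClusterCall:
    """A maximal run of above-cutoff bins merged into one interval."""

    arm: str
    start: int
    end: int
    peak_score: float
    genes: list[str]


def make_bins(
    arm_lengths: dict[str, int],
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Tile each arm with overlapping bins [i*step, min(i*step + width, L)).

    Bins start at 0 and advance by ``step`` until the start reaches the arm
    end, so every coordinate of every arm is covered; terminal bins are
    truncated at the arm end.
    """
    if not (width >= step > 0):
        raise ValueError(f"need width >= step > 0, got width={width}, step={step}")
    rows = []
    for arm, length in arm_lengths.items():
        if length <= 0:
            raise ValueError(f"arm {arm!r} has non-positive length {length}")
        start = 0
        while start < length:
            rows.append((arm, start, min(start + width, length)))
            start += step
    return pd.DataFrame(rows, columns=["arm", "start", "end"])


def select_top_fraction(
    deg_table: pd.DataFrame, q_frac: float = DEFAULT_FRACTION, by: str = "p"
) -> list[str]:
    """The floor(G * q_frac) most differentially expressed gene ids.

    Ranked by ascending per-gene p-value by default (``by="fold"`` ranks by
    descending |fold| instead); ties broken by larger |fold|, then gene id.
    """
    if deg_table.empty:
        raise ValueError("DEG table is empty")
    if not 0 < q_frac < 1:
        raise ValueError(f"q_frac must be in (0, 1), got {q_frac}")
    n_top = int(len(deg_table) * q_frac)
    tab = deg_table.reset_index().rename(columns={deg_table.index.name or "index": "gene"})
    tab["_absfold"] = tab["fold"].abs()
    if by == "p":
        tab = tab.sort_values(["p", "_absfold", "gene"], ascending=[True, False, True])
    elif by == "fold":
        tab = tab.sort_values(["_absfold", "p", "gene"], ascending=[False, True, True])
    else:
        raise ValueError(f"by must be 'p' or 'fold', got {by!r}")
    return tab["gene"].head(n_top).tolist()


def score_bins(
    grid: pd.DataFrame,
    catalog: GeneCatalog,
    top_set,
    p: float = DEFAULT_FRACTION,
) -> pd.DataFrame:
    """Count resident and flagged genes per bin and attach tail scores.

    A gene belongs to a bin iff its midpoint lies in [start, end).  Returns
    the grid with columns n (resident genes), k (top-set genes), p_binom
    (upper-tail probability of k among n at rate ``p``), and score
    = log10(1 / p_binom).
    """
    top_set = set(top_set)
    mids = catalog.midpoints()
    unknown = top_set - set(mids["gene"])
    if unknown:
        raise ValueError(f"top-set genes missing from catalog: {sorted(unknown)[:5]}")

    out = grid.copy()
    ns = np.zeros(len(out), dtype=int)
    ks = np.zeros(len(out), dtype=int)
    for arm, sub in mids.groupby("arm"):
        rows = np.flatnonzero((out["arm"] == arm).to_numpy())
        if rows.size == 0:
            continue
        sub_top = sub["gene"].isin(top_set).to_numpy()
        order = np.argsort(sub["midpoint"].to_numpy(), kind="mergesort")
        pos = sub["midpoint"].to_numpy()[order]
        top_pos = pos[sub_top[order]]
        starts = out["start"].to_numpy()[rows]
        ends = out["end"].to_numpy()[rows]
        ns[rows] = np.searchsorted(pos, ends, side="left") - np.searchsorted(pos, starts, side="left")
        ks[rows] = np.searchsorted(top_pos, ends, side="left") - np.searchsorted(top_pos, starts, side="left")
    out["n"] = ns
    out["k"] = ks
    out["p_binom"] = [binomial_tail(k, n, p) for k, n in zip(ks, ns)]
    out["score"] = np.log10(1.0 / out["p_binom"])
    return out


def call_clusters(
    track: pd.DataFrame,
    catalog: GeneCatalog,
    top_set,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ClusterCall]:
    """Merge runs of bins scoring strictly above ``cutoff`` into clusters.

    Overlapping or touching flagged bins on the same arm merge into one
    interval; member genes are the top-set genes whose midpoint falls in the
    merged interval.
    """
    top_set = set(top_set)
    mids = catalog.midpoints()
    calls: list[ClusterCall] = []
    flagged = track[track["score"] > cutoff]
    for arm, sub in flagged.groupby("arm", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        cur_peak = 0.0
        for _, row in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end, cur_peak = row["start"], row["end"], row["score"]
            elif row["start"] <= cur_end:
                cur_end = max(cur_end, row["end"])
                cur_peak = max(cur_peak, row["score"])
            else:
                calls.append(_finish(arm, cur_start, cur_end, cur_peak, mids, top_set))
                cur_start, cur_end, cur_peak = row["start"], row["end"], row["score"]
        if cur_start is not None:
            calls.append(_finish(arm, cur_start, cur_end, cur_peak, mids, top_set))
    return calls


def _finish(arm, start, end, peak, mids, top_set) -> ClusterCall:
    inside = mids[
        (mids["arm"] == arm) & (mids["midpoint"] >= start) & (mids["midpoint"] < end)
    ]
    members = sorted(g for g in inside["gene"] if g in top_set)
    return ClusterCall(arm=arm, start=int(start), end=int(end), peak_score=float(peak), genes=members)


def to_bedgraph(track: pd.DataFrame, name: str = "cluster_scan") -> str:
    """Render the score track as a BedGraph string for genome browsers.

    Each bin contributes one line at its own interval; overlapping bins are
    emitted as-is (browsers overlay them), mirroring the overlapping-bin scan.
    """
    lines = [f'track type=bedGraph name="{name}"']
    for _, row in track.iterrows():
        lines.append(f"{row['arm']}\t{int(row['start'])}\t{int(row['end'])}\t{row['score']:.4f}")
    return "\n".join(lines) + "\n"
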