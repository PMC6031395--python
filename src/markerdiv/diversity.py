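"""Sliding-window taxon richness and phylogenetic diversity.

Fragments aligned onto reference columns are sliced into 100-column windows
(step 10); members with gaps at more than 10% of window sites, or not
spanning the window, are discarded.  Window members are greedily clustered
into OTUs at fixed amino-acid identity cutoffs (70/80/90%), richness is
rarefied by resampling without replacement (10 replicates), richness curves
are compared with a two-sample log-rank test, and per-window PD is the total
branch length of a neighbor-joining tree of subsampled members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from ._model import GAP
from .phylo import neighbor_joining, pairwise_distances, total_branch_length
from .profile_hmm import AlignedFragment

__all__ = [
    "WindowSlice",
    "OTUClustering",
    "RarefactionCurve",
    "LogRankResult",
    "slice_window",
    "cluster_otus",
    "rarefy",
    "compare_richness_logrank",
    "richness_profile",
    "pd_profile",
]


@dataclass
class WindowSlice:
    group: str
    start_col: int
    width: int
    members: dict[str, str]  # fragment_id -> width-column string (gaps allowed)


@dataclass
class OTUClustering:
    identity_cutoff: float
    clusters: dict[str, list[str]]  # centroid id -> member ids (centroid first)
    order: list[str]  # processing order used by the greedy pass

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.clusters.values())

    def member_otu_index(self) -> tuple[list[str], np.ndarray]:
        """Flattened member ids with their OTU index."""
        ids, idx = [], []
        for k, (_, members) in enumerate(self.clusters.items()):
            ids.extend(members)
            idx.extend([k] * len(members))
        return ids, np.array(idx, dtype=np.int64)


@dataclass
class RarefactionCurve:
    group: str
    depths: list[int]
    mean_otus: list[float]
    n_replicates: int
    seed: int


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------


def window_string(frag: AlignedFragment, start: int, width: int) -> str:
    """The fragment's residues over columns [start, start+width), '-' elsewhere."""
    out = [GAP] * width
    for col, res in zip(frag.column_map, frag.residues):
        if col is not None and start <= col < start + width:
            out[col - start] = res
    return "".join(out)


def slice_window(
    aligned_fragments: list[AlignedFragment],
    start: int,
    width: int = 100,
    max_gap_frac: float = 0.10,
    group: str = "",
) -> WindowSlice:
    """Window members: fragments spanning [start, start+width) whose gap
    fraction inside the window does not exceed ``max_gap_frac``.

    The boundary is inclusive: with width 100 and the default threshold,
    exactly 10 gap columns are retained and 11 are discarded.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    end = start + width
    members: dict[str, str] = {}
    for frag in aligned_fragments:
        first, last = frag.span
        if first > start or last < end - 1:
            continue
        s = window_string(frag, start, width)
        gaps = s.count(GAP)
        if gaps <= max_gap_frac * width:
            members[frag.fragment_id] = s
    return WindowSlice(group=group, start_col=start, width=width, members=members)


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    """Matches over columns ungapped in both; 0 if no shared columns.

    The denominator choice (mutually ungapped window columns) is the
    package's documented reading of pairwise identity for gapped windows.
    """
    both = (a != ord(GAP)) & (b != ord(GAP))
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float(((a == b) & both).sum()) / n


def cluster_otus(
    window: WindowSlice, cutoff: float, order: list[str] | None = None
) -> OTUClustering:
    """Greedy centroid clustering at an identity cutoff.

    Sequences are processed in decreasing ungapped-length order (ties by id),
    mirroring length-sorted greedy clustering; each sequence joins the first
    existing centroid with identity >= cutoff, else founds a new cluster.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    ids = list(window.members)
    enc = {
        fid: np.frombuffer(window.members[fid].encode(), dtype=np.uint8) for fid in ids
    }
    if order is None:
        order = sorted(ids, key=lambda f: (-(enc[f] != ord(GAP)).sum(), f))
    centroids: list[str] = []
    clusters: dict[str, list[str]] = {}
    for fid in order:
        placed = False
        for cid in centroids:
            if _identity(enc[fid], enc[cid]) >= cutoff:
                clusters[cid].append(fid)
                placed = True
                break
        if not placed:
            centroids.append(fid)
            clusters[fid] = [fid]
    return OTUClustering(identity_cutoff=cutoff, clusters=clusters, order=list(order))


def rarefy(
    clustering: OTUClustering,
    depths: list[int],
    n_replicates: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean OTU count among d members sampled without replacement.

    Sampling is over sequences against the fixed clustering (cluster once,
    then subsample), the standard OTU rarefaction convention.  Each replicate
    draws one random permutation of the members and reads every depth as its
    first d entries: the per-depth marginal is still a uniform d-subset, and
    every replicate's curve — hence the mean curve — is exactly
    non-decreasing in depth.
    """
    ids, otu_idx = clustering.member_otu_index()
    n = len(ids)
    for d in depths:
        if not (1 <= d <= n):
            raise ValueError(f"depth {d} out of range [1, {n}]")
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(depths))
    for _ in range(n_replicates):
        perm = otu_idx[rng.permutation(n)]
        seen: set[int] = set()
        cum = np.empty(n, dtype=np.int64)
        count = 0
        for i, o in enumerate(perm):
            if o not in seen:
                seen.add(int(o))
                count += 1
            cum[i] = count
        totals += [cum[d - 1] for d in depths]
    means = [float(v) for v in totals / n_replicates]
    return RarefactionCurve(
        group="", depths=list(depths), mean_otus=means,
        n_replicates=n_replicates, seed=seed,
    )


def compare_richness_logrank(
    clust_a: OTUClustering, clust_b: OTUClustering
) -> LogRankResult:
    """Two-sample log-rank test on OTU cluster-size distributions.

    Each OTU is a subject whose event time is its cluster size (all events
    observed, no censoring); the statistic is the standard (O-E)^2/V
    chi-squared with 1 df.
    """
    sizes_a = np.array([len(v) for v in clust_a.clusters.values()], dtype=float)
    sizes_b = np.array([len(v) for v in clust_b.clusters.values()], dtype=float)
    if sizes_a.size == 0 or sizes_b.size == 0:
        raise ValueError("both clusterings must contain at least one OTU")
    res = logrank_test(sizes_a, sizes_b)
    p = min(float(res.p_value), 1.0)
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=max(p, np.nextafter(0, 1)),
        n_a=int(sizes_a.size),
        n_b=int(sizes_b.size),
    )


# ---------------------------------------------------------------------------
# profiles along the alignment


def _window_starts(n_cols: int, width: int, step: int) -> list[int]:
    return list(range(0, n_cols - width + 1, step))


def _mix_seed(*parts: int) -> int:
    """Deterministic per-cell seed derived from integer coordinates."""
    h = 0
    for p in parts:
        h = (h * 1_000_003 + int(p) + 0x9E3779B9) % (2**31)
    return h


def richness_profile(
    aligned_by_group: dict[str, list[AlignedFragment]],
    n_cols: int,
    cutoffs: tuple[float, ...] = (0.70, 0.80, 0.90),
    width: int = 100,
    step: int = 10,
    resample_n: int = 1000,
    n_replicates: int = 10,
    max_gap_frac: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window, per-group OTU counts rarefied to a common depth.

    Windows where a group has fewer than ``resample_n`` qualifying members
    are flagged and carry NaN counts.  Output is keyed by (window, group,
    cutoff) with per-cell seeds, so results do not depend on processing
    order.
    """
    groups = sorted(aligned_by_group)
    rows = []
    for start in _window_starts(n_cols, width, step):
        for gi, g in enumerate(groups):
            sl = slice_window(
                aligned_by_group[g], start, width=width,
                max_gap_frac=max_gap_frac, group=g,
            )
            for ci, cutoff in enumerate(cutoffs):
                n_members = len(sl.members)
                if n_members < resample_n:
                    rows.append((start, g, cutoff, n_members, np.nan, True))
                    continue
                clust = cluster_otus(sl, cutoff)
                curve = rarefy(
                    clust, [resample_n], n_replicates=n_replicates,
                    seed=_mix_seed(seed, start, gi, ci),
                )
                rows.append((start, g, cutoff, n_members, curve.mean_otus[0], False))
    return pd.DataFrame(
        rows,
        columns=["window_start", "group", "cutoff", "n_members", "n_otus", "flagged"],
    )


def pd_profile(
    aligned_by_group: dict[str, list[AlignedFragment]],
    n_cols: int,
    width: int = 100,
    step: int = 10,
    n_subsample: int = 1000,
    max_gap_frac: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window, per-group phylogenetic diversity.

    For each window and group, up to ``n_subsample`` members are drawn
    without replacement, pairwise Poisson-corrected distances computed, a
    neighbor-joining tree built, and PD reported as its total branch length.
    Windows with fewer than 3 members are skipped (NaN, flagged); groups with
    fewer than ``n_subsample`` members use all members and are flagged.
    """
    groups = sorted(aligned_by_group)
    rows = []
    for start in _window_starts(n_cols, width, step):
        for gi, g in enumerate(groups):
            sl = slice_window(
                aligned_by_group[g], start, width=width,
                max_gap_frac=max_gap_frac, group=g,
            )
            ids = sorted(sl.members)
            if len(ids) < 3:
                rows.append((start, g, len(ids), np.nan, True))
                continue
            flagged = len(ids) < n_subsample
            rng = np.random.default_rng(_mix_seed(seed, start, gi, 7919))
            if len(ids) > n_subsample:
                take = rng.choice(len(ids), size=n_subsample, replace=False)
                ids = [ids[i] for i in sorted(take)]
            seqs = [sl.members[i] for i in ids]
            uniq = len(set(seqs))
            if uniq == 1:
                rows.append((start, g, len(ids), 0.0, flagged))
                continue
            dm, undefined = pairwise_distances(ids, seqs)
            if undefined:
                flagged = True
            if len(ids) == 2:
                score = float(dm.matrix[0, 1])
            else:
                tree = neighbor_joining(dm)
                score = total_branch_length(tree)
            rows.append((start, g, len(ids), score, flagged))
    return pd.DataFrame(
        rows, columns=["window_start", "group", "n_subsampled", "pd", "flagged"]
    )
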