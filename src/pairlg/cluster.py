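"""Group-level spatiotemporal cluster statistics with TFCE.

Per (channel, sample) paired t statistics of condition differences are
enhanced with threshold-free cluster enhancement (TFCE):

    TFCE(p) = sum_h  e_p(h)^E * h^H * dh,   h = dh, 2*dh, ..., max|t|

where e_p(h) is the extent (node count) of the spatiotemporal connected
component containing p at threshold h.  Connectivity couples montage
channel adjacency (same time point) with temporal adjacency (same channel,
consecutive samples).  Positive and negative parts of the map are enhanced
separately on absolute values and re-signed.

Significance comes from a sign-flip permutation null for paired designs:
each permutation randomly negates participants' difference waveforms and
records the maximum |TFCE| over the map (two-tailed via the absolute
value); the observed labeling is included in the null.  The significant
point mask is then reduced to reportable clusters that (a) contain at
least two mutually adjacent channels at some time point and (b) persist
for at least 20 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GroupData", "Cluster", "ClusterResult",
    "paired_t_map", "tfce", "permutation_test", "report_representative",
    "Lattice",
]

#: Cap replacing infinite t at zero-variance, nonzero-mean cells.
T_CAP = 1e6


@dataclass
class GroupData:
    """Per-participant condition-averaged waveforms for a paired contrast."""

    cond_a: np.ndarray              # (participants, channels, samples)
    cond_b: np.ndarray
    times: np.ndarray               # ms
    channels: tuple[str, ...]
    adjacency: np.ndarray           # (channels, channels) bool

    def __post_init__(self):
        if self.cond_a.shape != self.cond_b.shape:
            raise ValueError("condition arrays must share one shape")

    @property
    def n_participants(self) -> int:
        return self.cond_a.shape[0]

    def differences(self) -> np.ndarray:
        return self.cond_a - self.cond_b


@dataclass
class Cluster:
    onset_ms: float
    offset_ms: float
    channels: tuple[str, ...]
    peak_stat: float                # signed peak enhanced statistic
    peak_latency_ms: float
    p_value: float
    polarity: int                   # +1 / -1

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha: float
    n_permutations: int
    threshold: float                # (1 - alpha) quantile of the null max
    tfce_map: np.ndarray            # (channels, samples), signed
    p_map: np.ndarray               # pointwise max-statistic p values
    sig_mask: np.ndarray            # pointwise significance before reporting filters
    null_max: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    adjacency: np.ndarray


def paired_t_map(group: GroupData) -> np.ndarray:
    """Paired t statistic per (channel, sample); d.f. = n - 1."""
    if group.n_participants < 2:
        raise ValueError("need at least 2 participants for a paired t map")
    return _t_from_diffs(group.differences())


def _pseudo_t_from_diffs(d: np.ndarray, v0: float | None = None) -> np.ndarray:
    """Variance-smoothed (pseudo-) t: m / sqrt((v + v0) / n), v0 = median map
    variance.  Regularization removes the near-zero-variance spikes that
    otherwise dominate max-statistic nulls at small cohort sizes; the map is
    recomputed with its own v0 for every permutation, so the statistic is
    one fixed function of the (signed) data."""
    n = d.shape[0]
    m = d.mean(axis=0)
    v = d.var(axis=0, ddof=1)
    if v0 is None:
        v0 = float(np.median(v))
    if v0 == 0 and (v == 0).all():
        return np.where(m == 0, 0.0, np.sign(m) * T_CAP)
    return m / np.sqrt((v + v0) / n)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn("zero-variance cells in paired t map; capping statistics",
                      RuntimeWarning, stacklevel=2)
        t = np.where(zero_var & (m == 0), 0.0, t)
        t = np.where(zero_var & (m != 0), np.sign(m) * T_CAP, t)
    return t


class Lattice:
    """Spatiotemporal connectivity of a channels x samples map.

    Node ``ch * n_times + t`` connects to spatial neighbors at the same
    sample and to the same channel at adjacent samples.  Prebuilt once and
    reused across the permutations of a test.
    """

    def __init__(self, adjacency: np.ndarray, n_times: int):
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if (adjacency != adjacency.T).any() or np.diag(adjacency).any():
            raise ValueError("adjacency must be symmetric with no self-edges")
        self.n_ch = adjacency.shape[0]
        self.n_times = int(n_times)
        self.adjacency = adjacency
        n = self.n_ch * self.n_times
        ci, cj = np.nonzero(np.triu(adjacency, 1))
        tt = np.arange(self.n_times)
        rows = np.concatenate([
            (ci[:, None] * self.n_times + tt[None, :]).ravel(),
            (np.arange(self.n_ch)[:, None] * self.n_times + tt[None, :-1]).ravel(),
        ])
        cols = np.concatenate([
            (cj[:, None] * self.n_times + tt[None, :]).ravel(),
            (np.arange(self.n_ch)[:, None] * self.n_times + tt[None, 1:]).ravel(),
        ])
        self.edges = (rows.astype(np.int64), cols.astype(np.int64))
        both_r = np.concatenate([rows, cols])
        both_c = np.concatenate([cols, rows])
        order = np.argsort(both_r, kind="stable")
        self.indices = both_c[order].astype(np.int64)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.indptr, both_r + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)
        self.spatial_pairs = np.column_stack([ci, cj])

    def component_labels(self, mask_flat: np.ndarray) -> tuple[int, np.ndarray]:
        rows, cols = self.edges
        keep = mask_flat[rows] & mask_flat[cols]
        n = mask_flat.size
        g = csr_matrix((np.ones(keep.sum(), dtype=np.int8),
                        (rows[keep], cols[keep])), shape=(n, n))
        return connected_components(g, directed=False)


@njit(cache=True)
def _tfce_kernel(vals, order, indptr, indices, n_steps_h, dh, E, H, out):
    n = vals.size
    parent = np.full(n, -1, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    ptr = 0
    for j in range(n_steps_h, 0, -1):
        h = dh * j
        while ptr < n and vals[order[ptr]] >= h:
            u = order[ptr]
            parent[u] = u
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if parent[v] != -1:
                    # union u's root with v's root (by size)
                    ru = u
                    while parent[ru] != ru:
                        ru = parent[ru]
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
            ptr += 1
        hterm = h ** H * dh
        for i in range(ptr):
            u = order[i]
            r = u
            while parent[r] != r:
                r = parent[r]
            # path compression
            w = u
            while parent[w] != r:
                nxt = parent[w]
                parent[w] = r
                w = nxt
            out[u] += size[r] ** E * hterm


def tfce(stat_map: np.ndarray, adjacency: np.ndarray | Lattice,
         e: float = 0.5, h: float = 2.0, dh: float | None = None,
         n_steps: int = 50) -> np.ndarray:
    """Threshold-free cluster enhancement of a channels x samples map.

    ``dh`` defaults to max|map| / n_steps.  Signs are processed separately
    on absolute values and re-signed; scaling the input up can only
    increase enhanced magnitudes.
    """
    stat_map = np.asarray(stat_map, dtype=np.float64)
    if stat_map.size == 0:
        raise ValueError("empty statistic map")
    lat = adjacency if isinstance(adjacency, Lattice) else Lattice(
        adjacency, stat_map.shape[1])
    amax = np.abs(stat_map).max()
    out = np.zeros(stat_map.size)
    if amax == 0:
        return out.reshape(stat_map.shape)
    if dh is None:
        dh = amax / n_steps
    if dh <= 0:
        raise ValueError("dh must be > 0")
    for sign in (1.0, -1.0):
        vals = np.where(sign * stat_map > 0, np.abs(stat_map), 0.0).ravel()
        vmax = vals.max()
        if vmax == 0:
            continue
        n_steps_h = int(np.floor(vmax / dh + 1e-12))
        if n_steps_h == 0:
            continue
        order = np.argsort(-vals, kind="stable")
        part = np.zeros(vals.size)
        _tfce_kernel(vals, order, lat.indptr, lat.indices,
                     n_steps_h, dh, e, h, part)
        out += sign * part
    return out.reshape(stat_map.shape)


def permutation_test(group: GroupData, n_perm: int = 1000, alpha: float = 0.05,
                     seed: int | None = None, e: float = 0.5, h: float = 2.0,
                     n_steps: int = 50, min_duration_ms: float = 20.0,
                     min_adjacent_channels: int = 2,
                     var_smooth: bool = True,
                     exhaustive: bool | None = None) -> ClusterResult:
    """Sign-flip max-|TFCE| permutation test with cluster reporting filters.

    With ``var_smooth`` (default) the enhanced statistic is the variance-
    smoothed pseudo-t; ``var_smooth=False`` uses the raw paired t.  When all
    2**n sign patterns fit in the permutation budget the null is enumerated
    exhaustively (the observed labeling is then included by construction);
    otherwise patterns are sampled and the observed labeling is entered as
    the first null element, as is standard.
    """
    if group.n_participants < 2:
        raise ValueError("need at least 2 participants")
    if group.adjacency is None:
        raise ValueError("channel adjacency is required")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p values will be coarse",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    d = group.differences()
    n, n_ch, n_t = d.shape
    lat = Lattice(group.adjacency, n_t)
    stat = _pseudo_t_from_diffs if var_smooth else _t_from_diffs

    t_obs = stat(d)
    tfce_obs = tfce(t_obs, lat, e=e, h=h, n_steps=n_steps)

    if exhaustive is None:
        exhaustive = 2**n <= n_perm
    if exhaustive and 2**n > 4 * n_perm:
        raise ValueError("exhaustive enumeration infeasible at this cohort size")
    if exhaustive:
        sign_sets = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2.0 - 1.0
    else:
        sign_sets = np.concatenate([
            np.ones((1, n)),                       # observed labeling first
            rng.choice(np.array([-1.0, 1.0]), size=(n_perm - 1, n)),
        ])
    null_max = np.empty(len(sign_sets))
    for i, signs in enumerate(sign_sets):
        t_map = stat(signs[:, None, None] * d) if i or exhaustive else t_obs
        enhanced = tfce(t_map, lat, e=e, h=h, n_steps=n_steps)
        null_max[i] = np.abs(enhanced).max()
    n_perm = len(sign_sets)

    sorted_null = np.sort(null_max)
    flat_abs = np.abs(tfce_obs).ravel()
    p_map = (n_perm - np.searchsorted(sorted_null, flat_abs, side="left")) / n_perm
    p_map = p_map.reshape(n_ch, n_t)
    sig = p_map <= alpha
    threshold = float(np.quantile(null_max, 1 - alpha))

    clusters = _extract_clusters(tfce_obs, p_map, sig, lat, group,
                                 min_duration_ms, min_adjacent_channels)
    return ClusterResult(clusters=clusters, alpha=alpha, n_permutations=n_perm,
                         threshold=threshold, tfce_map=tfce_obs, p_map=p_map,
                         sig_mask=sig, null_max=null_max, times=group.times,
                         channel_labels=tuple(group.channels),
                         adjacency=group.adjacency)


def _extract_clusters(tfce_obs, p_map, sig, lat: Lattice, group: GroupData,
                      min_duration_ms, min_adjacent_channels) -> list[Cluster]:
    times = np.asarray(group.times, dtype=float)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = sig & (sign * tfce_obs > 0)
        if not mask.any():
            continue
        n_comp, labels = lat.component_labels(mask.ravel())
        comp_ids = np.unique(labels[mask.ravel()])
        for cid in comp_ids:
            node_mask = (labels == cid) & mask.ravel()
            mask2d = node_mask.reshape(mask.shape)
            ch_idx, t_idx = np.nonzero(mask2d)
            onset, offset = times[t_idx.min()], times[t_idx.max()]
            if offset - onset < min_duration_ms:
                continue
            if min_adjacent_channels >= 2 and not _has_adjacent_pair(mask2d, lat):
                continue
            vals = tfce_obs[mask2d]
            peak = np.argmax(np.abs(vals))
            clusters.append(Cluster(
                onset_ms=float(onset), offset_ms=float(offset),
                channels=tuple(group.channels[i] for i in np.unique(ch_idx)),
                peak_stat=float(vals[peak]),
                peak_latency_ms=float(times[t_idx[peak]]),
                p_value=float(p_map[mask2d].min()),
                polarity=sign))
    clusters.sort(key=lambda c: c.onset_ms)
    return clusters


def _has_adjacent_pair(mask2d: np.ndarray, lat: Lattice) -> bool:
    """True if >= 2 mutually adjacent channels co-occur at some time point."""
    for i, j in lat.spatial_pairs:
        if (mask2d[i] & mask2d[j]).any():
            return True
    return False


@dataclass
class RepresentativeCluster:
    channel: str
    present: bool
    onset_ms: float | None = None
    offset_ms: float | None = None
    peak_stat: float | None = None
    peak_latency_ms: float | None = None
    p_value: float | None = None


def report_representative(result: ClusterResult, channel: str,
                          ) -> list[RepresentativeCluster]:
    """Restrict each cluster to one electrode's time course (Fz or Pz style)."""
    if channel not in result.channel_labels:
        raise KeyError(f"unknown channel {channel!r}")
    ci = result.channel_labels.index(channel)
    out = []
    times = np.asarray(result.times, dtype=float)
    for cl in result.clusters:
        in_cluster = (result.sig_mask[ci]
                      & (cl.polarity * result.tfce_map[ci] > 0)
                      & (times >= cl.onset_ms) & (times <= cl.offset_ms))
        if channel not in cl.channels or not in_cluster.any():
            out.append(RepresentativeCluster(channel=channel, present=False))
            continue
        t_idx = np.nonzero(in_cluster)[0]
        vals = result.tfce_map[ci, t_idx]
        peak = np.argmax(np.abs(vals))
        out.append(RepresentativeCluster(
            channel=channel, present=True,
            onset_ms=float(times[t_idx.min()]), offset_ms=float(times[t_idx.max()]),
            peak_stat=float(vals[peak]), peak_latency_ms=float(times[t_idx[peak]]),
            p_value=cl.p_value))
    return out
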