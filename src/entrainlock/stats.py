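"""Statistical battery for phase-locking maps.

Centrepiece is the nonparametric cluster-based permutation test over
(electrode x frequency x time) matrices: elementwise paired t-values are
thresholded at uncorrected p < 0.05, suprathreshold samples are grouped
into clusters connected over montage-adjacent electrodes and contiguous
frequency/time bins, each cluster is scored by its summed t, and observed
clusters are compared with the permutation distribution of the maximum
(minimum) cluster score under within-participant condition-label flips.
Positive and negative clusters are tested against their own signed nulls,
each at the 97.5th percentile (two-tailed 5%).

Supporting tests: exact binomial comparison of significant-electrode
counts, one-way ANOVA over pulse levels, Dunnett's many-to-one post-hoc
against the baseline control, and the Pearson trend of phase locking over
pulses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats as spstats
from scipy.sparse.csgraph import connected_components


@dataclass
class Cluster:
    sign: int                 # +1 or -1
    indices: np.ndarray       # flat voxel indices into the (c, f, t) grid
    sum_t: float
    p: float
    significant: bool


@dataclass
class ClusterResult:
    """Observed t-map, clusters and the signed permutation nulls."""

    t_map: np.ndarray                  # (n_ch, n_f, n_t)
    df: int
    t_crit: float
    clusters: list[Cluster]
    null_pos: np.ndarray               # per-permutation max positive sum-t
    null_neg: np.ndarray               # per-permutation min negative sum-t
    n_perm: int
    exhaustive: bool
    alpha_percentile: float = 97.5
    channels: list[str] = field(default_factory=list)
    freqs_hz: np.ndarray = None
    times_s: np.ndarray = None

    @property
    def masked_t_map(self) -> np.ndarray:
        """t-values inside significant clusters; zero elsewhere."""
        out = np.zeros_like(self.t_map)
        flat = out.reshape(-1)
        tflat = self.t_map.reshape(-1)
        for c in self.clusters:
            if c.significant:
                flat[c.indices] = tflat[c.indices]
        return out

    def significance_mask(self) -> np.ndarray:
        mask = np.zeros(self.t_map.size, dtype=bool)
        for c in self.clusters:
            if c.significant:
                mask[c.indices] = True
        return mask.reshape(self.t_map.shape)


@dataclass
class SigCountMap:
    """Number of electrodes inside significant clusters per (f, t)."""

    counts: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    n_channels: int

    def mean_over_window(self, t_lo: float, t_hi: float) -> np.ndarray:
        sel = (self.times_s >= t_lo) & (self.times_s <= t_hi)
        return self.counts[:, sel].mean(axis=1)


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray,
                 p_thresh: float = 0.05):
    """Elementwise paired t over participants (axis 0).

    Returns ``(t_map, df, t_crit)``; zero-variance voxels are NaN (a
    warning is emitted).  Shapes of the two stacks must agree.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition stacks must have identical shapes "
                         "(same participants, same axes)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need >= 3 participants")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    nonzero_mean = degenerate & (mean != 0)
    if nonzero_mean.any():
        warnings.warn("zero-variance voxels with nonzero difference: t "
                      "undefined, masked as NaN", RuntimeWarning,
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, np.where(mean == 0, 0.0, np.nan), t)
    df = n - 1
    t_crit = float(spstats.t.ppf(1.0 - p_thresh / 2.0, df))
    return t, df, t_crit


def grid_adjacency(n_ch: int, n_f: int, n_t: int,
                   chan_adj: np.ndarray) -> sparse.csr_matrix:
    """Sparse adjacency over the flattened (channel, freq, time) grid.

    Neighbours: +/-1 time bin, +/-1 frequency bin (same channel), and
    montage-adjacent channels at the same (f, t).
    """
    idx = np.arange(n_ch * n_f * n_t).reshape(n_ch, n_f, n_t)
    rows, cols = [], []
    # time neighbours
    rows.append(idx[:, :, :-1].ravel()); cols.append(idx[:, :, 1:].ravel())
    # frequency neighbours
    rows.append(idx[:, :-1, :].ravel()); cols.append(idx[:, 1:, :].ravel())
    # channel neighbours
    ci, cj = np.nonzero(np.triu(chan_adj, k=1))
    if len(ci):
        rows.append(idx[ci].ravel()); cols.append(idx[cj].ravel())
    r = np.concatenate(rows); c = np.concatenate(cols)
    n = n_ch * n_f * n_t
    a = sparse.coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)),
                          shape=(n, n))
    return (a + a.T).tocsr()


def _cluster_sums(t_flat: np.ndarray, mask: np.ndarray,
                  adj: sparse.csr_matrix,
                  return_members: bool = False):
    """Sum-t per connected component of the suprathreshold mask."""
    nodes = np.flatnonzero(mask)
    if len(nodes) == 0:
        return ([], []) if return_members else []
    sub = adj[nodes][:, nodes]
    n_comp, labels = connected_components(sub, directed=False)
    sums = np.bincount(labels, weights=t_flat[nodes], minlength=n_comp)
    if return_members:
        members = [nodes[labels == k] for k in range(n_comp)]
        return list(sums), members
    return list(sums)


def _sign_matrix(n_part: int, n_perm: int, seed: int
                 ) -> tuple[np.ndarray, bool]:
    """Within-participant label-flip signs; exhaustive when feasible."""
    if 2**n_part <= n_perm:
        warnings.warn(
            f"only 2^{n_part} = {2**n_part} distinct sign patterns exist; "
            "enumerating exhaustively", RuntimeWarning, stacklevel=3)
        bits = ((np.arange(2**n_part)[:, None] >> np.arange(n_part)) & 1)
        return bits * 2 - 1, True
    rng = np.random.default_rng(seed)
    return rng.choice([-1, 1], size=(n_perm, n_part)), False


def cluster_permutation(cond_a: np.ndarray, cond_b: np.ndarray,
                        adjacency: np.ndarray, n_perm: int = 500,
                        seed: int = 0, p_thresh: float = 0.05,
                        alpha_percentile: float = 97.5,
                        channels: list[str] | None = None,
                        freqs_hz: np.ndarray | None = None,
                        times_s: np.ndarray | None = None) -> ClusterResult:
    """Cluster-based permutation test between two paired condition stacks.

    ``cond_a``/``cond_b``: (n_participants, n_ch, n_f, n_t) arrays.
    ``adjacency``: boolean channel adjacency (n_ch, n_ch).  The null is
    built from within-participant condition flips (sign flips of the
    paired differences); exhaustive enumeration replaces sampling when
    2^n_participants <= n_perm.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    t_map, df, t_crit = paired_t_map(a, b, p_thresh)
    n_part = a.shape[0]
    n_ch, n_f, n_t = t_map.shape
    adj = grid_adjacency(n_ch, n_f, n_t, np.asarray(adjacency, dtype=bool))

    d = (a - b).reshape(n_part, -1)
    ss = (d**2).sum(axis=0)
    t_flat = np.nan_to_num(t_map.reshape(-1), nan=0.0)

    pos_sums, pos_members = _cluster_sums(t_flat, t_flat > t_crit, adj,
                                          return_members=True)
    neg_sums, neg_members = _cluster_sums(t_flat, t_flat < -t_crit, adj,
                                          return_members=True)

    signs, exhaustive = _sign_matrix(n_part, n_perm, seed)
    n_eff = len(signs)
    null_pos = np.zeros(n_eff)
    null_neg = np.zeros(n_eff)
    chunk = 128
    for start in range(0, n_eff, chunk):
        s = signs[start:start + chunk]
        mean = (s @ d) / n_part
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (ss[None, :] - n_part * mean**2) / (n_part - 1)
            t_perm = mean / np.sqrt(var / n_part)
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=0.0, neginf=0.0)
        for j in range(len(s)):
            row = t_perm[j]
            ps = _cluster_sums(row, row > t_crit, adj)
            ns = _cluster_sums(row, row < -t_crit, adj)
            null_pos[start + j] = max(ps) if ps else 0.0
            null_neg[start + j] = min(ns) if ns else 0.0

    thr_pos = np.percentile(null_pos, alpha_percentile)
    thr_neg = np.percentile(null_neg, 100.0 - alpha_percentile)

    def _count_ge(null, s):
        # ties to fp precision count: the identity permutation recomputes
        # the observed statistic through a different expression
        return np.sum((null > s) | np.isclose(null, s, rtol=1e-9,
                                              atol=1e-9))

    clusters: list[Cluster] = []
    for sum_t, members in zip(pos_sums, pos_members):
        p = (1.0 + _count_ge(null_pos, sum_t)) / (n_eff + 1.0)
        clusters.append(Cluster(sign=1, indices=members, sum_t=float(sum_t),
                                p=float(p), significant=sum_t > thr_pos))
    for sum_t, members in zip(neg_sums, neg_members):
        p = (1.0 + _count_ge(-null_neg, -sum_t)) / (n_eff + 1.0)
        clusters.append(Cluster(sign=-1, indices=members,
                                sum_t=float(sum_t), p=float(p),
                                significant=sum_t < thr_neg))
    return ClusterResult(t_map=t_map, df=df, t_crit=t_crit,
                         clusters=clusters, null_pos=null_pos,
                         null_neg=null_neg, n_perm=n_eff,
                         exhaustive=exhaustive,
                         alpha_percentile=alpha_percentile,
                         channels=channels or [], freqs_hz=freqs_hz,
                         times_s=times_s)


def count_significant_electrodes(result: ClusterResult) -> SigCountMap:
    """Per (frequency, time): number of channels covered by any
    significant cluster (each channel counted once)."""
    mask = result.significance_mask()
    counts = mask.sum(axis=0)
    return SigCountMap(counts=counts, freqs_hz=result.freqs_hz,
                       times_s=result.times_s,
                       n_channels=result.t_map.shape[0])


def binomial_freq_test(count_at_stim_f: int, count_at_other_f: int) -> float:
    """Exact two-sided binomial test of the stimulation-frequency count
    against p0 = 0.5 of the combined count (minlike two-sided rule)."""
    k, other = int(count_at_stim_f), int(count_at_other_f)
    if k < 0 or other < 0:
        raise ValueError("counts must be >= 0")
    n = k + other
    if n == 0:
        warnings.warn("both counts zero: binomial test undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(spstats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def anova_pulse(table: np.ndarray) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA over pulse levels.

    ``table``: participants x levels (levels = ctrl, pulse 1..n_pulses).
    Returns (F, df1, df2, p); df1 = levels - 1, df2 = levels * (n - 1).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("table must be (participants >= 2) x levels")
    if np.isnan(x).any():
        raise ValueError("missing cells in the pulse table")
    n, k = x.shape
    grand = x.mean()
    ss_between = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_within = ((x - x.mean(axis=0)) ** 2).sum()
    df1, df2 = k - 1, k * (n - 1)
    if ss_within == 0:
        warnings.warn("zero within-level variance: F undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), df1, df2, float("nan")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(spstats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def dunnett_vs_ctrl(table: np.ndarray, seed: int | None = None
                    ) -> np.ndarray:
    """Dunnett many-to-one comparisons of each pulse level against ctrl.

    ``table``: participants x levels with the control in column 0.
    Returns family-corrected two-sided p-values for columns 1..k-1.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("table must be (participants >= 2) x (levels >= 2)")
    if np.isnan(x).any():
        raise ValueError("missing cells in the pulse table")
    rng = np.random.default_rng(seed) if seed is not None else None
    res = spstats.dunnett(*(x[:, j] for j in range(1, x.shape[1])),
                          control=x[:, 0], alternative="two-sided",
                          random_state=rng)
    return np.asarray(res.pvalue)


def pearson_trend(pulse_index: np.ndarray,
                  values: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between pulse number and phase locking over all
    (participant, pulse) points, with the standard t-based p."""
    k = np.asarray(pulse_index, dtype=float).ravel()
    v = np.asarray(values, dtype=float).ravel()
    if len(k) != len(v) or len(k) < 3:
        raise ValueError("need >= 3 (pulse, value) pairs")
    if np.std(k) == 0 or np.std(v) == 0:
        warnings.warn("zero variance: correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    r, p = spstats.pearsonr(k, v)
    return float(r), float(p)


def peak_response_frequency(values: np.ndarray, freqs_hz: np.ndarray,
                            times_s: np.ndarray, window: tuple[float, float],
                            channel_index: int = 0) -> float:
    """Frequency maximising the time-averaged statistic in a window.

    ``values``: (n_ch, n_f, n_t).  Ties resolve to the lowest frequency
    (argmax takes the first index on an ascending grid).
    """
    sel = (times_s >= window[0]) & (times_s <= window[1])
    if not sel.any():
        raise ValueError("window contains no samples")
    seg = values[channel_index][:, sel]
    prof = np.nanmean(seg, axis=1)
    if np.isnan(prof).all():
        raise ValueError("window is fully masked")
    return float(freqs_hz[int(np.nanargmax(prof))])
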