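"""Circular binary segmentation of absolute test-statistic tracks.

CBS treats the values of the current interval as lying on a circle and looks
for the pair of cut points that maximizes the pooled two-sample t-statistic
between the arc and its complement.  A split is accepted when its
within-interval permutation p-value is at most ``alpha``; accepted splits are
applied recursively to the resulting pieces.  Here the algorithm runs on the
per-chromosome track of |t| statistics from the probe-level density models,
so detected mean shifts mark probe runs with unusual association strength.

Candidate segments are those with at least three probes and a mean |t|
above 1 (and, by default, above the chromosome-wide mean |t|); candidates are
expanded by six times their probe count on each side before permutation
inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import ProbeMap


@dataclass(frozen=True)
class CBSParams:
    """Split-acceptance tuning: permutation test per candidate split."""

    alpha: float = 0.01
    n_split_permutations: int = 1000
    min_width: int = 2
    early_stop: bool = True

    def __post_init__(self) -> None:
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_split_permutations < 1:
            raise ValueError("n_split_permutations must be >= 1")


@dataclass(frozen=True)
class Segment:
    chromosome: str
    start_idx: int  # global probe-map index, half-open
    end_idx: int
    mean_abs_t: float

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("segment end must exceed start")

    @property
    def n_probes(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(frozen=True)
class ExpandedRegion:
    segment: Segment
    exp_start_idx: int
    exp_end_idx: int

    def __post_init__(self) -> None:
        if not (self.exp_start_idx <= self.segment.start_idx):
            raise ValueError("expansion must not start after the segment")
        if not (self.exp_end_idx >= self.segment.end_idx):
            raise ValueError("expansion must not end before the segment")

    @property
    def n_total_probes(self) -> int:
        return self.exp_end_idx - self.exp_start_idx


@lru_cache(maxsize=128)
def _pair_indices(m: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All circular cut pairs (i, j), i < j, with both arcs >= min_width.

    Enumerated in lexicographic (i, j) order so that the first argmax is the
    leftmost, shortest arc (deterministic tie-break).
    """
    ii, jj = [], []
    for i in range(m):
        for j in range(i + min_width, m + 1):
            # arc [i, j) has length j - i; its circular complement m - (j - i)
            if j - i <= m - min_width:
                ii.append(i)
                jj.append(j)
    return np.asarray(ii, dtype=np.intp), np.asarray(jj, dtype=np.intp)


def _pair_between_ss(csum: np.ndarray, ii, jj, m: int) -> np.ndarray:
    """Between-arc sum of squares for each cut pair; rows = batch sequences.

    For the pooled-variance two-sample t between an arc and its complement,
    |t|² = (m − 2)·B / (SS_tot − B) where B is the between-group sum of
    squares and SS_tot the interval's total sum of squares.  SS_tot is
    invariant under permutation of the interval, so maximizing |t| over cut
    pairs — and comparing shuffled maxima against an observed one — can be
    done entirely on the B scale from prefix sums alone.
    """
    n1 = (jj - ii).astype(float)
    n2 = m - n1
    tot = csum[:, -1][:, None]
    s1 = csum[:, jj] - csum[:, ii]
    u = s1 / n1 - (tot - s1) / n2
    return (n1 * n2 / m) * u * u


def _prefix(values: np.ndarray) -> np.ndarray:
    z = np.zeros((values.shape[0], 1))
    return np.concatenate([z, np.cumsum(values, axis=1)], axis=1)


def _total_ss(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.sum((v - v.mean()) ** 2))


def _t_from_between_ss(b: float, ss_tot: float, m: int) -> float:
    if ss_tot <= 0 or b <= 0:
        return 0.0
    if b >= ss_tot:
        return np.inf
    return float(np.sqrt(max(m - 2, 1) * b / (ss_tot - b)))


def _between_ss_from_t(t: float, ss_tot: float, m: int) -> float:
    if not np.isfinite(t):
        return ss_tot
    t2 = t * t
    return ss_tot * t2 / (max(m - 2, 1) + t2)


def best_circular_split(
    values: np.ndarray, min_width: int = 2
) -> tuple[int, int, float]:
    """Cut pair (i, j) maximizing |t| between arc and complement, and that |t|.

    Ties break toward the leftmost, then shortest, arc.  Returns (-1, -1, 0.0)
    when the interval is too short to split.
    """
    v = np.asarray(values, dtype=float)[None, :]
    m = v.shape[1]
    if m < 2 * min_width:
        return -1, -1, 0.0
    ii, jj = _pair_indices(m, min_width)
    b = _pair_between_ss(_prefix(v), ii, jj, m)[0]
    bmax = float(b.max())
    # a partition has two (i, j) representations whose computed statistics can
    # differ by rounding; take the first pair within tolerance of the maximum
    k = int(np.argmax(b >= bmax - 1e-9 * max(bmax, 1e-300)))
    tmax = _t_from_between_ss(float(b[k]), _total_ss(v[0]), m)
    return int(ii[k]), int(jj[k]), tmax


def _max_split_stats_batch(batch: np.ndarray, min_width: int) -> np.ndarray:
    """Maximal between-arc SS over all cut pairs, per batch row.

    Iterates over arc lengths with contiguous prefix-sum slices (cheaper than
    gathering all pairs at once); only the maximum is needed here, so the
    argmax tie-break of :func:`best_circular_split` does not apply.
    """
    m = batch.shape[1]
    csum = _prefix(batch)
    tot = csum[:, -1][:, None]
    best = np.zeros(batch.shape[0])
    for L in range(min_width, m - min_width + 1):
        n2 = m - L
        s1 = csum[:, L:] - csum[:, : m - L + 1]
        u = s1 / L - (tot - s1) / n2
        b = (L * n2 / m) * np.max(u * u, axis=1)
        np.maximum(best, b, out=best)
    return best


def split_permutation_pvalue(
    values: np.ndarray,
    observed: float,
    params: CBSParams,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for the best split of an interval.

    Shuffles the interval's values; ties (permuted max-|t| equal to the
    observed) count as exceedances.  With ``early_stop`` the shuffle loop
    aborts once acceptance at ``alpha`` is impossible, returning the
    (conservative) p-value estimate from the shuffles done so far.
    """
    v = np.asarray(values, dtype=float)
    m = len(v)
    B = params.n_split_permutations
    obs_ss = _between_ss_from_t(observed, _total_ss(v), m)
    reject_count = int(np.ceil(params.alpha * (B + 1)))  # count+1 > this => p > alpha
    pair_count = max(len(_pair_indices(m, params.min_width)[0]), 1)
    chunk = int(np.clip(8_000_000 // pair_count, 16, B))
    exceed = 0
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perms = rng.permuted(np.broadcast_to(v, (b, m)), axis=1)
        stats = _max_split_stats_batch(perms, params.min_width)
        exceed += int(np.sum(stats >= obs_ss * (1 - 1e-12)))
        done += b
        if params.early_stop and exceed + 1 > reject_count:
            return (exceed + 1) / (done + 1)
    return (exceed + 1) / (B + 1)


def cbs_segment(
    values: np.ndarray,
    params: CBSParams = CBSParams(),
    rng: np.random.Generator | int | None = 0,
) -> list[int]:
    """Recursive CBS change-point detection; returns sorted interior boundaries.

    Boundaries are 0-based offsets into ``values``; a boundary b separates
    ``values[..b)`` from ``values[b..)``.  Constant input, or input shorter
    than twice the minimum arc width, yields no change-points.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("track values must be finite")
    boundaries: list[int] = []
    stack = [(0, len(v))]
    while stack:
        a, b = stack.pop()
        seg = v[a:b]
        if len(seg) < 2 * params.min_width:
            continue
        i, j, tmax = best_circular_split(seg, params.min_width)
        if tmax <= 0:
            continue
        p = split_permutation_pvalue(seg, tmax, params, rng)
        if p > params.alpha:
            continue
        cuts = sorted({c for c in (i, j) if 0 < c < len(seg)})
        if not cuts:
            continue
        boundaries.extend(a + c for c in cuts)
        edges = [0] + cuts + [len(seg)]
        for lo, hi in zip(edges, edges[1:]):
            stack.append((a + lo, a + hi))
    return sorted(boundaries)


def segments_from_boundaries(
    values: np.ndarray, boundaries: list[int], chromosome: str, offset: int = 0
) -> list[Segment]:
    """Convert interior boundaries into contiguous Segments with mean |t|."""
    edges = [0] + list(boundaries) + [len(values)]
    out = []
    for lo, hi in zip(edges, edges[1:]):
        if hi > lo:
            out.append(
                Segment(
                    chromosome=chromosome,
                    start_idx=offset + lo,
                    end_idx=offset + hi,
                    mean_abs_t=float(np.mean(values[lo:hi])),
                )
            )
    return out


def identify_candidate_segments(
    track: np.ndarray,
    probe_map: ProbeMap,
    params: CBSParams = CBSParams(),
    min_probes: int = 3,
    min_mean_t: float = 1.0,
    chromosome_mean_guard: bool = True,
    seed: int = 0,
) -> list[Segment]:
    """CBS per chromosome on |t|, then the candidate filters.

    A segment qualifies when it spans at least ``min_probes`` probes and its
    mean |t| strictly exceeds ``min_mean_t``.  The chromosome-mean guard
    additionally requires the segment mean to exceed the chromosome-wide
    mean |t|, which keeps long flat tracks (whole-chromosome "segments") from
    qualifying spuriously.
    """
    values = np.abs(np.asarray(track, dtype=float))
    if len(values) != probe_map.n_probes:
        raise ValueError("track length does not match probe map")
    ss = np.random.SeedSequence(seed)
    out: list[Segment] = []
    bounds = probe_map.chromosome_bounds()
    for chrom, child in zip(probe_map.chromosomes, ss.spawn(len(bounds))):
        s, e = bounds[chrom]
        chrom_vals = values[s:e]
        rng = np.random.default_rng(child)
        cps = cbs_segment(chrom_vals, params, rng)
        chrom_mean = float(np.mean(chrom_vals))
        for seg in segments_from_boundaries(chrom_vals, cps, chrom, offset=s):
            if seg.n_probes < min_probes or seg.mean_abs_t <= min_mean_t:
                continue
            if chromosome_mean_guard and seg.mean_abs_t <= chrom_mean:
                continue
            out.append(seg)
    return out


def expand_segment(
    segment: Segment,
    chromosome_bounds: tuple[int, int],
    expansion: int = 6,
) -> ExpandedRegion:
    """Pad a segment by ``expansion`` times its probe count on each side.

    Unclipped, a k-probe segment grows to (2*expansion + 1) * k probes; the
    expansion is clipped at the chromosome boundaries and the reported total
    reflects the clipping.
    """
    lo, hi = chromosome_bounds
    if not (lo <= segment.start_idx and segment.end_idx <= hi):
        raise ValueError("segment lies outside the chromosome bounds")
    pad = expansion * segment.n_probes
    return ExpandedRegion(
        segment=segment,
        exp_start_idx=max(lo, segment.start_idx - pad),
        exp_end_idx=min(hi, segment.end_idx + pad),
    )
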