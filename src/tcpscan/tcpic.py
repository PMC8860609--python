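"""TCP-IC: the maximal information coefficient applied to anchor-aligned
footprint signal matrices.

The statistic asks whether, around a set of anchor positions (start codons,
upstream AUGs, motif sites), the mean footprint signal depends *jointly* on
position and footprint length.  The pipeline is:

1. :func:`build_signal` - average the per-gene RC matrices over anchors,
   aligned on the anchor and normalized by per-offset gene coverage;
2. :func:`discretize_fixed` / :func:`discretize_optimized` - threshold each
   footprint-length row, turning the grey-scale matrix into a binary point
   set of surviving (offset, length) cells;
3. :func:`mic` - the maximal information coefficient of that point set:
   over all x-by-y grids with x*y <= B(n) = max(4, floor(n^0.6)), the
   maximum of (best achievable mutual information) / log2(min(x, y)),
   MI in bits;
4. :func:`permutation_pvalue` - an empirical null obtained by shuffling the
   offset axis and repeating steps 2-3;
5. :func:`equalize_points` - the threshold-inflation control that aligns the
   surviving point counts of compared signals.

For n <= 40 points the MIC maximization is exact: all cut placements on one
axis are enumerated and the other axis is optimized by an exact dynamic
program (the conditional-entropy objective is additive over bins).  For
larger n a MINE-style approximation equipartitions the smaller axis and
optimizes the other by the same dynamic program, in both orientations.
:func:`mic_brute_force` is an independent full enumeration used as the test
oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

EXACT_MAX_N = 40
EPSILON = 1e-5

__all__ = [
    "SignalMatrix", "BinarySignal", "MicResult", "build_signal",
    "discretize_fixed", "discretize_optimized", "mask_points", "mic",
    "mic_brute_force", "permutation_pvalue", "equalize_points", "r_equivalent",
]


@dataclass
class SignalMatrix:
    """Anchor-aligned, coverage-normalized mean RC matrix."""

    values: np.ndarray          # (n_lengths, n_offsets), >= 0
    coverage: np.ndarray        # (n_offsets,) anchors covering each offset
    lengths: np.ndarray         # footprint lengths (rows)
    offsets: np.ndarray         # anchor-relative offsets (columns)
    n_anchors: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lengths), len(self.offsets)):
            raise ValueError("signal shape inconsistent with axes")
        if (self.values < 0).any():
            raise ValueError("signal values must be non-negative")


@dataclass
class BinarySignal:
    """Per-row thresholded signal: mask[r, c] = values[r, c] > thresholds[r]."""

    mask: np.ndarray            # bool, same shape as the signal
    thresholds: np.ndarray      # (n_lengths,)

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())


@dataclass
class MicResult:
    mic: float
    x_bins: int
    y_bins: int
    n_points: int
    p_value: float | None = None
    mode: str | None = None
    thresholds: np.ndarray | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# signal construction and discretization
# ---------------------------------------------------------------------------

def build_signal(
    profiles: dict,
    anchors: list[tuple[str, int]],
    halfwidth: int = 50,
    lengths: tuple[int, int] = (15, 100),
) -> SignalMatrix:
    """Mean RC around anchors, normalized by per-offset anchor coverage.

    ``S[len, o]`` averages ``RC[len, anchor + o]`` over the anchors whose
    transcript actually covers offset ``o``; offsets outside a transcript
    contribute to neither numerator nor denominator (anchors near transcript
    ends would otherwise bias edge columns downward).
    """
    if not anchors:
        raise ValueError("empty anchor set")
    lo, hi = lengths
    lens = np.arange(lo, hi + 1)
    offs = np.arange(-halfwidth, halfwidth + 1)
    num = np.zeros((len(lens), len(offs)))
    cov = np.zeros(len(offs), dtype=int)
    from .profiles import MIN_LEN  # row indexing of GeneProfile

    rows = lens - MIN_LEN
    for gene, pos in anchors:
        prof = profiles[gene]
        L = prof.n_positions
        o_lo = max(-halfwidth, -pos)
        o_hi = min(halfwidth, L - 1 - pos)
        if o_hi < o_lo:
            continue
        sl = slice(o_lo + halfwidth, o_hi + halfwidth + 1)
        cov[sl] += 1
        num[:, sl] += prof.matrix[rows, pos + o_lo : pos + o_hi + 1]
    vals = np.divide(num, cov, out=np.zeros_like(num), where=cov > 0)
    return SignalMatrix(vals, cov, lens, offs, n_anchors=len(anchors))


_FIXED_MODES = ("mean", "2mean", "mean_std", "median")


def discretize_fixed(signal: SignalMatrix, mode: str = "mean") -> BinarySignal:
    """Threshold each footprint-length row by a summary of its own values.

    Modes: row mean, twice the mean, mean plus standard deviation, median.
    The mask keeps strictly-greater cells, so constant rows survive nowhere.
    """
    V = signal.values
    if mode == "mean":
        t = V.mean(axis=1)
    elif mode == "2mean":
        t = 2.0 * V.mean(axis=1)
    elif mode == "mean_std":
        t = V.mean(axis=1) + V.std(axis=1)
    elif mode == "median":
        t = np.median(V, axis=1)
    else:
        raise ValueError(f"unknown discretization mode {mode!r}; use {_FIXED_MODES}")
    return BinarySignal(mask=V > t[:, None], thresholds=t)


def mask_points(signal: SignalMatrix, bsig: BinarySignal) -> tuple[np.ndarray, np.ndarray]:
    """Surviving cells as (x = offset, y = footprint length) coordinate arrays."""
    r, c = np.nonzero(bsig.mask)
    return signal.offsets[c].astype(float), signal.lengths[r].astype(float)


def _mask_mic(signal: SignalMatrix, mask: np.ndarray) -> float:
    r, c = np.nonzero(mask)
    if r.size == 0:
        return 0.0
    return mic(signal.offsets[c].astype(float), signal.lengths[r].astype(float)).mic


def discretize_optimized(signal: SignalMatrix, max_sweeps: int = 5) -> BinarySignal:
    """Per-row thresholds chosen to maximize the whole-matrix MIC.

    Coordinate ascent: thresholds start at the row means and rows are swept
    in ascending footprint length; each row's candidate set is its own unique
    values plus +inf (empty row).  A candidate is adopted only on a strict
    MIC improvement, so ties keep the current threshold; sweeps repeat until
    a full pass changes nothing.
    """
    V = signal.values
    t = V.mean(axis=1).astype(float)
    best = _mask_mic(signal, V > t[:, None])
    for _ in range(max_sweeps):
        changed = False
        for r in range(V.shape[0]):
            candidates = np.unique(V[r])
            candidates = np.concatenate([candidates, [np.inf]])
            for cand in candidates:
                if cand == t[r]:
                    continue
                t_try = t.copy()
                t_try[r] = cand
                score = _mask_mic(signal, V > t_try[:, None])
                if score > best:
                    best = score
                    t = t_try
                    changed = True
        if not changed:
            break
    return BinarySignal(mask=V > t[:, None], thresholds=t)


# ---------------------------------------------------------------------------
# MIC core
# ---------------------------------------------------------------------------

def grid_bound(n: int) -> int:
    """Max grid area B(n) = max(4, floor(n^0.6)); a 2x2 grid is always allowed."""
    return max(4, int(math.floor(n ** 0.6)))


def _xlogx(v: np.ndarray) -> np.ndarray:
    return v * np.log2(np.where(v > 0, v, 1.0))


def _axis_bounds(sorted_vals: np.ndarray) -> np.ndarray:
    """Prefix positions [0, ..., n] at which the sorted value changes."""
    change = np.nonzero(np.diff(sorted_vals))[0] + 1
    return np.concatenate([[0], change, [len(sorted_vals)]])


def _dp_max_mi(bounds: np.ndarray, ybin: np.ndarray, ky: int, kx_max: int,
               n: int) -> np.ndarray:
    """Exact max MI (bits) for 2..kx_max x-bins, given a fixed y-binning.

    ``bounds`` are the admissible cut prefix positions along x (between
    distinct x values) for points already sorted by x; ``ybin`` assigns each
    point (same order) to one of ``ky`` y-bins.  Uses MI = H(Y) - H(Y|X)
    and the additivity of -n*H(Y|X) over x-bins.

    Returns an array ``mi`` where ``mi[k]`` is the maximum over partitions
    into exactly k non-empty x-bins (NaN where k exceeds the number of
    distinct x values).
    """
    m = len(bounds) - 1                      # number of distinct x values
    # cumulative y-bin counts at each admissible boundary
    seg_idx = np.repeat(np.arange(m), np.diff(bounds))
    cum = np.zeros((m + 1, ky))
    np.add.at(cum, (seg_idx + 1, ybin), 1.0)
    cum = np.cumsum(cum, axis=0)
    tot = bounds.astype(float)

    ny = cum[-1]
    p = ny[ny > 0] / n
    h_y = float(-(p * np.log2(p)).sum())

    # F[s, t] = sum_y c*log2(c) - tot*log2(tot) for the bin (bounds[s], bounds[t]]
    diff = cum[None, :, :] - cum[:, None, :]          # (m+1, m+1, ky)
    tdiff = tot[None, :] - tot[:, None]
    F = _xlogx(diff).sum(axis=-1) - _xlogx(tdiff)

    kx_max = min(kx_max, m)
    mi = np.full(kx_max + 1, np.nan)
    s_idx = np.arange(m + 1)
    invalid = s_idx[:, None] >= s_idx[None, :]        # need s < t
    dp = F[0].copy()                                  # k = 1, dp[t] over (0, t]
    for k in range(2, kx_max + 1):
        A = dp[:, None] + F
        A[invalid] = -np.inf
        dp = A.max(axis=0)
        mi[k] = h_y + dp[m] / n
    return mi


def _equipartition_bins(bounds: np.ndarray, k: int, n: int) -> np.ndarray:
    """Choose k-1 admissible cut prefixes nearest to equal point mass."""
    interior = bounds[1:-1]
    if len(interior) == 0:
        return np.array([], dtype=int)
    targets = np.arange(1, k) * n / k
    idx = np.searchsorted(interior, targets)
    lo = interior[np.maximum(idx - 1, 0)]
    hi = interior[np.minimum(idx, len(interior) - 1)]
    cuts = np.where(np.abs(lo - targets) <= np.abs(hi - targets), lo, hi)
    return np.unique(cuts)


def _prepare(x: np.ndarray, y: np.ndarray):
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    xb = _axis_bounds(xs)
    return xs, ys, xb


def _ybin_from_cuts(ys_sorted_by_x: np.ndarray, y_cut_values: np.ndarray) -> np.ndarray:
    # cut value v separates {<= v} from {> v}: equal values stay in the lower
    # bin, so every gap between adjacent distinct values is realizable
    return np.searchsorted(y_cut_values, ys_sorted_by_x, side="left")


def _mic_exact(x: np.ndarray, y: np.ndarray, bound: int) -> MicResult:
    """Exact MIC: enumerate y-axis cut sets, optimize x by the exact DP."""
    n = len(x)
    best, best_shape = 0.0, (2, 2)
    # enumerate ky over the y axis only: the DP is exact in x, so every
    # (kx, ky) shape is covered exactly.
    _, ys, xb = _prepare(x, y)
    uy = np.unique(y)
    my = len(uy)
    for ky in range(2, bound // 2 + 1):
        if ky > my:
            break
        kx_max = bound // ky
        if kx_max < 2:
            break
        # cut between consecutive distinct y values: choose ky-1 of my-1 gaps
        for gaps in itertools.combinations(range(my - 1), ky - 1):
            cut_vals = uy[list(gaps)]          # cut after these values
            ybin = _ybin_from_cuts(ys, cut_vals)
            mi = _dp_max_mi(xb, ybin, ky, kx_max, n)
            for kx in range(2, len(mi)):
                if np.isnan(mi[kx]):
                    continue
                val = mi[kx] / math.log2(min(kx, ky))
                if val > best:
                    best, best_shape = val, (kx, ky)
    return MicResult(min(best, 1.0), best_shape[0], best_shape[1], n)


def _mic_approx(x: np.ndarray, y: np.ndarray, bound: int) -> MicResult:
    """MINE-style approximation: equipartition one axis, DP-optimize the other."""
    n = len(x)
    best, best_shape = 0.0, (2, 2)
    for flip, (ax_opt, ax_eq) in enumerate([(x, y), (y, x)]):
        _, eq_sorted, opt_bounds = _prepare(ax_opt, ax_eq)
        m_eq = len(np.unique(ax_eq))
        eq_bounds = _axis_bounds(np.sort(ax_eq))
        sorted_eq_vals = np.sort(ax_eq)
        for k_eq in range(2, min(bound // 2, m_eq) + 1):
            k_opt_max = bound // k_eq
            if k_opt_max < 2:
                break
            cut_prefixes = _equipartition_bins(eq_bounds, k_eq, n)
            if len(cut_prefixes) == 0:
                continue
            cut_vals = sorted_eq_vals[cut_prefixes - 1]
            ybin = _ybin_from_cuts(eq_sorted, cut_vals)
            ky = int(ybin.max()) + 1
            mi = _dp_max_mi(opt_bounds, ybin, ky, k_opt_max, n)
            for k_opt in range(2, len(mi)):
                if np.isnan(mi[k_opt]):
                    continue
                shape = (k_opt, k_eq) if flip == 0 else (k_eq, k_opt)
                val = mi[k_opt] / math.log2(min(k_opt, k_eq))
                if val > best:
                    best, best_shape = val, shape
    return MicResult(min(best, 1.0), best_shape[0], best_shape[1], n)


def mic(x, y) -> MicResult:
    """Maximal information coefficient of a 2-D point set.

    Exact for n <= 40 points; otherwise the equipartition/DP approximation
    (both orientations).  Degenerate sets (fewer than 2 points, or a single
    distinct value on both axes) score 0 by contract.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 2 or (len(np.unique(x)) < 2 and len(np.unique(y)) < 2):
        return MicResult(0.0, 0, 0, n, degenerate=True)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return MicResult(0.0, 2, 2, n)
    bound = grid_bound(n)
    if n <= EXACT_MAX_N:
        return _mic_exact(x, y, bound)
    return _mic_approx(x, y, bound)


def mic_brute_force(x, y, max_n: int = EXACT_MAX_N) -> MicResult:
    """Independent oracle: exhaustive enumeration of all cut placements.

    Enumerates every admissible grid shape and every choice of cut positions
    on both axes, scoring each grid from its contingency table.  Refuses
    point sets larger than ``max_n``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > max_n:
        raise ValueError(f"brute force limited to n <= {max_n}")
    if n < 2 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        deg = len(np.unique(x)) < 2 and len(np.unique(y)) < 2
        return MicResult(0.0, 0 if deg else 2, 0 if deg else 2, n, degenerate=deg)
    ux, dx = np.unique(x, return_inverse=True)
    uy, dy = np.unique(y, return_inverse=True)
    mx, my = len(ux), len(uy)
    bound = grid_bound(n)
    best, best_shape = 0.0, (2, 2)
    for kx in range(2, bound // 2 + 1):
        for ky in range(2, bound // kx + 1):
            for xcuts in itertools.combinations(range(1, mx), min(kx, mx) - 1):
                xbin = np.searchsorted(np.array(xcuts), dx, side="right")
                for ycuts in itertools.combinations(range(1, my), min(ky, my) - 1):
                    ybin = np.searchsorted(np.array(ycuts), dy, side="right")
                    C = np.zeros((len(xcuts) + 1, len(ycuts) + 1))
                    np.add.at(C, (xbin, ybin), 1.0)
                    P = C / n
                    px = P.sum(axis=1, keepdims=True)
                    py = P.sum(axis=0, keepdims=True)
                    nz = P > 0
                    mi_val = float((P[nz] * np.log2(P[nz] / (px @ py)[nz])).sum())
                    val = mi_val / math.log2(min(kx, ky))
                    if val > best:
                        best, best_shape = val, (kx, ky)
    return MicResult(min(best, 1.0), best_shape[0], best_shape[1], n)


# ---------------------------------------------------------------------------
# permutation null and point-count control
# ---------------------------------------------------------------------------

def signal_mic(signal: SignalMatrix, mode: str = "mean",
               equalize_to: int | None = None) -> MicResult:
    """Discretize a signal matrix and score it with MIC."""
    bsig = (discretize_optimized(signal) if mode == "optimized"
            else discretize_fixed(signal, mode))
    if equalize_to is not None:
        bsig = equalize_points(signal, bsig, equalize_to)
    xs, ys = mask_points(signal, bsig)
    res = mic(xs, ys)
    res.mode = mode
    res.thresholds = bsig.thresholds
    res.n_points = len(xs)
    return res


def permutation_pvalue(
    signal: SignalMatrix,
    mode: str = "mean",
    n_perm: int = 1000,
    seed: int = 0,
    per_row: bool = False,
    equalize_to: int | None = None,
) -> MicResult:
    """Empirical p-value by shuffling the offset (position) axis.

    Each replicate permutes the column order of the signal matrix (jointly
    across rows by default, preserving the per-offset length profile; with
    ``per_row`` each footprint-length row is permuted independently),
    re-discretizes with the same rule, and recomputes MIC.  The p-value is
    the fraction of replicates whose MIC *strictly* exceeds the observed one,
    so an all-degenerate signal returns p = 0 with the degenerate flag set.
    """
    rng = np.random.default_rng(seed)
    real = signal_mic(signal, mode=mode, equalize_to=equalize_to)
    n_cols = len(signal.offsets)
    exceed = 0
    for _ in range(n_perm):
        if per_row:
            V = np.empty_like(signal.values)
            for r in range(V.shape[0]):
                V[r] = signal.values[r, rng.permutation(n_cols)]
        else:
            V = signal.values[:, rng.permutation(n_cols)]
        perm_sig = SignalMatrix(V, signal.coverage, signal.lengths,
                                signal.offsets, signal.n_anchors)
        if signal_mic(perm_sig, mode=mode, equalize_to=equalize_to).mic > real.mic:
            exceed += 1
    real.p_value = exceed / n_perm
    real.degenerate = real.degenerate or real.mic == 0.0
    return real


def equalize_points(
    signal: SignalMatrix,
    bsig: BinarySignal,
    target_count: int,
    epsilon: float = EPSILON,
    method: str = "closed_form",
) -> BinarySignal:
    """Raise all row thresholds in epsilon steps until <= target_count points.

    Every iteration adds ``epsilon`` to every row's threshold; the process
    stops at the first step where the surviving-cell count is at or below the
    target.  ``method='walk'`` runs that loop literally; the default computes
    the identical stopping step in closed form (each cell survives step k iff
    k < ceil((S - t) / epsilon)).
    """
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    t0 = bsig.thresholds.astype(float)
    if bsig.n_points <= target_count:
        return BinarySignal(mask=bsig.mask.copy(), thresholds=t0.copy())
    V = signal.values
    if method == "walk":
        k = 0
        while True:
            k += 1
            mask = V > (t0 + k * epsilon)[:, None]
            if mask.sum() <= target_count:
                return BinarySignal(mask=mask, thresholds=t0 + k * epsilon)
    surv = V > t0[:, None]
    gaps = (V - t0[:, None])[surv]
    ks = np.ceil(gaps / epsilon).astype(np.int64)
    ks.sort()
    k_stop = int(ks[::-1][target_count])          # (target+1)-th largest step
    t_new = t0 + k_stop * epsilon
    return BinarySignal(mask=V > t_new[:, None], thresholds=t_new)


def r_equivalent(mic_score: float) -> float:
    """Correlation magnitude analogous to a MIC score: R = sqrt(MIC)."""
    if not 0.0 <= mic_score <= 1.0:
        raise ValueError("MIC must lie in [0, 1]")
    return math.sqrt(mic_score)
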