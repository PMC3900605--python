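"""Genome structure from read coverage: collapsed terminal-repeat detection,
tandem-repeat scanning, and linearization of a collapsed circular assembly.

A linear phage genome with identical long terminal repeats (LTRs) assembles
into a circle in which the repeat is collapsed to one copy carrying roughly
twice the read depth of the rest of the sequence. Detecting that elevated
segment recovers the repeat and lets the genome be rewritten as
unique sequence + one repeat copy, with total length =
unique_length + ltr_length.

All coordinates are 1-based inclusive and may wrap the circular origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import GenomeRecord


@dataclass
class CoverageProfile:
    """Per-position read depth over a circular sequence."""

    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class TandemRepeat:
    unit_length: int
    start: int  # 1-based inclusive
    end: int
    copies: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 2 * self.unit_length:
            raise ValueError("tandem repeat must span at least two unit copies")


@dataclass
class LTRCall:
    """An elevated-coverage segment interpreted as a collapsed terminal repeat."""

    start: int  # 1-based inclusive, circular
    end: int
    length: int
    coverage_ratio: float
    n_segments: int = 1
    flank_repeats: list = field(default_factory=list)


@dataclass
class LTRDetection:
    """Outcome of elevated-segment detection; ``call`` is None when no
    segment exceeds the threshold ("no LTR detected" is a result, not an
    error)."""

    call: LTRCall | None
    n_segments: int

    @property
    def detected(self) -> bool:
        return self.call is not None


@dataclass
class LinearizedGenome:
    unique_length: int
    ltr_length: int
    total_length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.total_length != self.unique_length + self.ltr_length:
            raise ValueError("total_length must equal unique_length + ltr_length")


def _circular_moving_average(depth: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0:
        window += 1
    pad = window // 2
    ext = np.concatenate([depth[-pad:], depth, depth[:pad]])
    kernel = np.ones(window) / window
    return np.convolve(ext, kernel, mode="valid")


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array, as (start, length)
    with 0-based starts; a run may wrap the origin."""
    n = len(mask)
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then runs cannot wrap
    shift = int(np.argmin(mask))
    rolled = np.roll(mask, -shift)
    edges = np.flatnonzero(np.diff(rolled.astype(np.int8)))
    starts = edges[::2] + 1
    ends = np.append(edges[1::2] + 1, n)[: len(starts)]
    return [(int((s + shift) % n), int(e - s)) for s, e in zip(starts, ends)]


def _refine_ramp(depth2: np.ndarray, pos: int, window: int, rising: bool) -> int:
    """Least-squares flat-ramp-flat fit on raw depth around a boundary.

    The depth transition at a collapsed-repeat boundary is not a sharp step:
    every position within one read length of the boundary is covered by a
    read-length-wide mixture of single- and double-copy reads, so the profile
    climbs linearly from the background level to twice background. The
    boundary itself is the *foot* of that ramp (the last background-level
    position), so the fitted model is: flat low level, linear ramp of free
    width, flat high level; the reported changepoint is the ramp foot. A
    sharp step is recovered as the small-width limit of the ramp.

    ``depth2`` is the doubled depth array (so windows never wrap); ``pos`` is
    an index into the first copy, ``rising`` says whether depth climbs with
    increasing index here. Returns the refined foot index (mod L).
    """
    L = len(depth2) // 2
    lo, hi = pos - window, pos + window
    if lo < 0:
        lo += L
        pos += L
        hi += L
    seg = depth2[lo:hi].astype(float)
    if not rising:
        seg = seg[::-1]
    n = len(seg)
    s1 = np.concatenate([[0.0], np.cumsum(seg)])
    s2 = np.concatenate([[0.0], np.cumsum(seg**2)])
    sx = np.concatenate([[0.0], np.cumsum(seg * np.arange(n))])
    margin = 5
    widths = [w for w in (10, 25, 50, 100, 200, 300, 400, 600, 800, 1200)
              if w <= n - 2 * margin]
    best_sse, best_a, best_w = np.inf, pos - lo, 0
    for w in widths:
        a = np.arange(margin, n - w - margin)
        nl = a.astype(float)
        nr = (n - a - w).astype(float)
        sl, sr = s1[a], s1[-1] - s1[a + w]
        ql, qr = s2[a], s2[-1] - s2[a + w]
        low, high = sl / nl, sr / nr
        sse_l = ql - sl**2 / nl
        sse_r = qr - sr**2 / nr
        dsum = s1[a + w] - s1[a]
        dx = sx[a + w] - sx[a]
        qm = s2[a + w] - s2[a]
        delta = high - low
        # Sum over the ramp of t and t^2 with t_j = (j - a + 0.5) / w
        st = w / 2.0
        st2 = ((w - 1) * w * (2 * w - 1) / 6.0 + w * (w - 1) / 2.0 + w / 4.0) / w**2
        d_dot_lin = low * dsum + delta / w * (dx - (a - 0.5) * dsum)
        lin2 = w * low**2 + 2 * low * delta * st + delta**2 * st2
        sse = sse_l + sse_r + (qm - 2 * d_dot_lin + lin2)
        i = int(np.argmin(sse))
        if sse[i] < best_sse:
            best_sse, best_a, best_w = float(sse[i]), int(a[i]), w
    if rising:
        return (lo + best_a) % L, best_w
    return (hi - best_a) % L, best_w


def detect_elevated_segment(
    profile: CoverageProfile,
    smoothing_window: int = 201,
    ratio_threshold: float = 1.5,
    refine_window: int | None = None,
) -> LTRDetection:
    """Find the collapsed-LTR candidate segment in a circular depth profile.

    The depth is smoothed with a circular moving average; the single maximal
    contiguous circular segment whose smoothed depth is at least
    ``ratio_threshold`` times the global median is returned (the longest one
    when several disjoint segments qualify, with the count reported).
    Boundaries are then refined by a least-squares flat-ramp-flat fit on the
    raw depth within ``refine_window`` of each threshold crossing (the
    changepoint is the ramp foot, since read-length edge effects turn the
    two-level depth step into a linear ramp), and the coverage ratio is
    computed on raw depths inside vs outside the call.
    """
    depth = profile.depth
    L = len(depth)
    if L < 10 * smoothing_window:
        raise ValueError("profile too short for the smoothing window")
    if refine_window is None:
        refine_window = 4 * smoothing_window
    smoothed = _circular_moving_average(depth, smoothing_window)
    med = float(np.median(smoothed))
    if med <= 0:
        return LTRDetection(call=None, n_segments=0)
    mask = smoothed >= ratio_threshold * med
    runs = _circular_runs(mask)
    runs = [r for r in runs if r[1] < L]  # a fully-elevated circle is no contrast
    if not runs:
        return LTRDetection(call=None, n_segments=0)
    runs.sort(key=lambda r: (-r[1], r[0]))
    s0, run_len = runs[0]
    e0 = (s0 + run_len) % L  # exclusive

    depth2 = np.concatenate([depth, depth])
    w = min(refine_window, max(run_len // 2 - 1, 1), (L - run_len) // 2 - 1)
    ramp_s = ramp_e = 0
    if w >= 2:
        s0, ramp_s = _refine_ramp(depth2, s0, w, rising=True)
        e0, ramp_e = _refine_ramp(depth2, e0 if e0 > 0 else L, w, rising=False)
    length = (e0 - s0) % L
    if length == 0:
        return LTRDetection(call=None, n_segments=len(runs))

    inside = np.zeros(L, dtype=bool)
    if s0 < e0:
        inside[s0:e0] = True
    else:
        inside[s0:] = True
        inside[:e0] = True
    # the fitted edge ramps are single/double-copy mixtures; the copy-number
    # fold is the plateau level over background, so measure the inside mean
    # on the segment interior between the ramp tops when one exists
    interior = inside.copy()
    if ramp_s + ramp_e < length:
        for k in range(ramp_s):
            interior[(s0 + k) % L] = False
        for k in range(1, ramp_e + 1):
            interior[(e0 - k) % L] = False
    mean_in = float(depth[interior].mean())
    mean_out = float(depth[~inside].mean())
    ratio = mean_in / mean_out if mean_out > 0 else np.inf
    end_1based = e0 if e0 >= 1 else L  # inclusive end = exclusive end in 1-based
    call = LTRCall(
        start=s0 + 1,
        end=end_1based,
        length=length,
        coverage_ratio=ratio,
        n_segments=len(runs),
    )
    return LTRDetection(call=call, n_segments=len(runs))


# ---------------------------------------------------------------------------
# tandem repeats


def _max_windows(bad: np.ndarray, budget_frac: float, unit: int) -> list[tuple[int, int]]:
    """Maximal windows [i, j) over a mismatch indicator array such that
    (# mismatches) <= budget_frac * (window + unit). Two-pointer scan."""
    n = len(bad)
    csum = np.concatenate([[0], np.cumsum(bad)])
    windows: list[tuple[int, int]] = []
    left = 0
    prev = None
    for right in range(n):
        if bad[right] and budget_frac == 0:
            left = right + 1
            continue
        while csum[right + 1] - csum[left] > budget_frac * (right + 1 - left + unit):
            left += 1
        if left <= right:
            if prev is not None and prev[0] == left:
                prev = (left, right + 1)
                windows[-1] = prev
            else:
                prev = (left, right + 1)
                windows.append(prev)
    # drop windows contained in a later, larger one
    out = []
    for w in windows:
        if out and w[0] <= out[-1][0] and w[1] >= out[-1][1]:
            out[-1] = w
        elif not out or w[1] > out[-1][1]:
            out.append(w)
    return out


def find_tandem_repeats(
    sequence: str,
    unit_min: int = 1,
    unit_max: int = 10,
    min_total: int = 20,
    max_mismatch_frac: float = 0.0,
) -> list[TandemRepeat]:
    """Scan for maximal near-exact tandem runs.

    For each unit length u in [unit_min, unit_max], positions where
    seq[i] == seq[i+u] mark self-periodicity at lag u; maximal stretches with
    mismatch fraction <= ``max_mismatch_frac`` and total span >= ``min_total``
    are reported. A run is attributed to its smallest generating unit: a
    candidate whose span lies inside an already-accepted run with a smaller
    unit is discarded (so a homopolymer reports unit 1, not 2 or 4).
    """
    s = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    L = len(s)
    accepted: list[TandemRepeat] = []
    for u in range(unit_min, min(unit_max, L // 2) + 1):
        eq = s[: L - u] == s[u:]
        bad = ~eq
        for i, j in _max_windows(bad, max_mismatch_frac, u):
            total = (j - i) + u
            if total < max(min_total, 2 * u):
                continue
            start, end = i + 1, i + total  # 1-based inclusive
            covered = any(
                r.unit_length < u and r.start <= start and r.end >= end for r in accepted
            )
            if covered:
                continue
            accepted.append(
                TandemRepeat(unit_length=u, start=start, end=end, copies=total / u)
            )
    accepted.sort(key=lambda r: (r.start, r.unit_length))
    return accepted


def flank_tandem_repeats(
    sequence: str, call: LTRCall, window: int = 200, **repeat_kwargs
) -> list[TandemRepeat]:
    """Tandem repeats within ``window`` bp of either boundary of an LTR call,
    reported in the coordinates of the (circular) input sequence."""
    L = len(sequence)
    doubled = sequence + sequence
    found: list[TandemRepeat] = []
    for boundary in (call.start - 1, call.end % L):
        lo = boundary - window
        offset = lo % L
        chunk = doubled[offset : offset + 2 * window]
        for r in find_tandem_repeats(chunk, **repeat_kwargs):
            start0 = (r.start - 1 + offset) % L
            end0 = start0 + (r.end - r.start)
            if end0 >= L:  # repeats wrapping the origin are not re-reported
                continue
            found.append(
                TandemRepeat(
                    unit_length=r.unit_length,
                    start=start0 + 1,
                    end=end0 + 1,
                    copies=r.copies,
                )
            )
    unique = {(r.unit_length, r.start, r.end): r for r in found}
    return sorted(unique.values(), key=lambda r: (r.start, r.unit_length))


# ---------------------------------------------------------------------------
# linearization


def rotate_sequence(sequence: str, offset: int) -> str:
    """Rotate a circular sequence left by ``offset`` (0-based)."""
    offset %= len(sequence)
    return sequence[offset:] + sequence[:offset]


def linearize(collapsed: GenomeRecord, call: LTRCall) -> LinearizedGenome:
    """Rewrite a collapsed circular assembly as a linear genome starting at
    the first base of the collapsed repeat.

    The rotated sequence is the unique sequence plus one repeat copy; the
    full linear molecule carries the repeat at both ends, so
    total_length = unique_length + ltr_length.
    """
    seq = rotate_sequence(collapsed.sequence, call.start - 1)
    return LinearizedGenome(
        unique_length=len(seq),
        ltr_length=call.length,
        total_length=len(seq) + call.length,
        sequence=seq,
    )
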