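"""Independent oracles used by the tests.

Kept deliberately separate from the package implementation: the brute-force
capture distribution enumerates every dendrite assignment instead of
convolving Bernoullis, and the axis search below is a plain double loop over
a finer spherical grid.
"""

import numpy as np


def brute_force_capture_pmf(counts, p: float = 0.5) -> np.ndarray:
    """PMF of the captured-cell count by enumerating all 2**sum(counts)
    dendrite-class assignments (island bit = 1)."""
    counts = [int(k) for k in counts]
    S = int(sum(counts))
    n = len(counts)
    A = np.arange(2**S, dtype=np.uint64)
    ones = np.bitwise_count(A).astype(np.int64)
    weights = (p**ones) * ((1.0 - p) ** (S - ones))
    captured = np.zeros(len(A), dtype=np.int64)
    off = 0
    for k in counts:
        mask = np.uint64((1 << k) - 1)
        bits = (A >> np.uint64(off)) & mask
        captured += ((bits == 0) | (bits == mask)).astype(np.int64)
        off += k
    return np.bincount(captured, weights=weights, minlength=n + 1)


def grid_gap_search(points_a, points_b, step_deg: float):
    """Plain exhaustive projection-gap search over a theta/phi grid,
    orienting the axis so set a precedes set b.  Returns (axis, gap)."""
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    best_gap = -np.inf
    best_axis = None
    thetas = np.deg2rad(np.arange(0.0, 180.0 + step_deg / 2, step_deg))
    phis = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    for th in thetas:
        for ph in phis:
            u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
            pa, pb = a @ u, b @ u
            g_fwd = pb.min() - pa.max()
            g_rev = pa.min() - pb.max()
            if g_fwd > best_gap:
                best_gap, best_axis = g_fwd, u.copy()
            if g_rev > best_gap:
                best_gap, best_axis = g_rev, -u
            if th < 1e-12 or abs(th - np.pi) < 1e-12:
                break  # poles: phi degenerate
    return best_axis, float(best_gap)
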