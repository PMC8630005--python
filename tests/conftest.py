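"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (direct summation, exhaustive search)
and stay independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from smpet.config import CameraModel, SimulationConfig, TraceNoise


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def naive_correlate_symmetric(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """O(n k) direct-summation correlation with symmetric boundary padding."""
    half = (kernel.size - 1) // 2
    n = x.size

    def sample(i: int) -> float:
        # symmetric (edge-repeating) extension, valid for pads < n
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            else:
                i = 2 * n - i - 1
        return x[i]

    out = np.empty(n)
    for i in range(n):
        out[i] = sum(kernel[j + half] * sample(i + j) for j in range(-half, half + 1))
    return out


def exhaustive_change_points(x: np.ndarray, n_changes: int) -> list[int]:
    """Least-squares optimal piecewise-constant change points, brute force.

    A change point c means the new level starts at index c.  Feasible for
    n_changes <= 2 on short traces only.
    """
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(a: int, b: int) -> float:
        if b <= a:
            return 0.0
        s, s2 = csum[b] - csum[a], csum2[b] - csum2[a]
        return s2 - s * s / (b - a)

    best, best_cps = np.inf, []
    for cps in itertools.combinations(range(1, n), n_changes):
        bounds = [0, *cps, n]
        total = sum(sse(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if total < best - 1e-12:
            best, best_cps = total, list(cps)
    return best_cps


def brute_force_assignment(dist: np.ndarray, tol: float) -> int:
    """Minimum-total-distance one-to-one assignment size/cost by enumeration.

    Returns the maximum number of pairs with all pair distances <= tol,
    breaking ties by minimum total distance; used to vet greedy matching on
    tiny instances.
    """
    n1, n2 = dist.shape
    best_pairs, best_cost = 0, np.inf
    idx2 = list(range(n2))
    for k in range(min(n1, n2), -1, -1):
        found = False
        for rows in itertools.combinations(range(n1), k):
            for cols in itertools.permutations(idx2, k):
                d = [dist[r, c] for r, c in zip(rows, cols)]
                if all(v <= tol for v in d):
                    found = True
                    cost = sum(d)
                    if k > best_pairs or (k == best_pairs and cost < best_cost):
                        best_pairs, best_cost = k, cost
        if found:
            break
    return best_pairs


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_camera() -> CameraModel:
    return CameraModel(shape=(64, 64))


@pytest.fixture
def fast_sim_config() -> SimulationConfig:
    return SimulationConfig(n_molecules=20, duration_s=180.0, frame_interval_s=0.3,
                            k_close=1.0, k_open=5.0, p_uncoupled=0.1, seed=7)


@pytest.fixture
def noiseless() -> TraceNoise:
    return TraceNoise.noiseless()
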