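"""Independent reference implementations used only by the tests.

These deliberately avoid the package's enumeration code paths: profiles
come from exhaustive iteration over all 2^N occupancy bitmasks, and the
torsional term from a dense grid search over the interstrand helicity,
so agreement with the library is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np

from minicircle.sidd_model import EnergyParams


def occupancy_runs(occ: list[int]) -> list[tuple[int, int]]:
    """Maximal circular runs of 1s as (start, length)."""
    n = len(occ)
    if not any(occ):
        return []
    if all(occ):
        return [(0, n)]
    runs = []
    for s in range(n):
        if occ[s] and not occ[(s - 1) % n]:
            length = 0
            while occ[(s + length) % n]:
                length += 1
            runs.append((s, length))
    return runs


def grid_torsional_energy(
    n: int, alpha: float, n_bp: int, params: EnergyParams, tau_lim: float = 20.0,
    n_grid: int = 2_000_001,
) -> float:
    """Q(n, alpha) by brute-force minimisation over tau on a fine grid."""
    k = params.k_res(n_bp)
    if n == 0:
        return 0.5 * k * alpha * alpha
    tau = np.linspace(-tau_lim, tau_lim, n_grid)
    g = 0.5 * params.c_ss * n * tau**2 + 0.5 * k * (
        alpha + n / params.helicity_A - n * tau / (2 * math.pi)
    ) ** 2
    return float(g.min())


def brute_force_states(seq, alpha: float, params: EnergyParams):
    """All (occupancy, r, n, g) tuples of the restricted ensemble, via bitmasks."""
    n_bp = len(seq)
    n_max = params.resolved_n_max(n_bp)
    b = params.b_per_bp(seq)
    k = params.k_res(n_bp)

    def torsion(n):
        if n == 0:
            return 0.5 * k * alpha * alpha
        d = alpha + n / params.helicity_A
        return 0.5 * k * d * d / (1.0 + n * k / (4 * math.pi**2 * params.c_ss))

    states = []
    for mask in range(2**n_bp):
        occ = [(mask >> i) & 1 for i in range(n_bp)]
        n = sum(occ)
        if n > n_max:
            continue
        runs = occupancy_runs(occ)
        if len(runs) > params.r_max:
            continue
        g = (
            params.a_nuc * len(runs)
            + sum(b[i] for i in range(n_bp) if occ[i])
            + torsion(n)
        )
        states.append((occ, len(runs), n, g))
    return states


def brute_force_profile(seq, alpha: float, params: EnergyParams) -> np.ndarray:
    """Per-bp marginals by exhaustive 2^N enumeration."""
    states = brute_force_states(seq, alpha, params)
    g_min = min(g for *_, g in states)
    rt = params.rt
    z = 0.0
    m = np.zeros(len(seq))
    for occ, _, _, g in states:
        w = math.exp((g_min - g) / rt)
        z += w
        m += np.array(occ) * w
    return m / z


def brute_force_class_masses(seq, alpha: float, params: EnergyParams) -> dict:
    """Probability mass per (r, n) class by exhaustive enumeration."""
    states = brute_force_states(seq, alpha, params)
    g_min = min(g for *_, g in states)
    rt = params.rt
    z = 0.0
    masses: dict[tuple[int, int], float] = {}
    for _, r, n, g in states:
        w = math.exp((g_min - g) / rt)
        z += w
        masses[(r, n)] = masses.get((r, n), 0.0) + w
    return {key: val / z for key, val in masses.items()}


def brute_force_joint(seq, alpha: float, params: EnergyParams) -> np.ndarray:
    """Joint co-open probabilities (linear scale) by exhaustive enumeration."""
    states = brute_force_states(seq, alpha, params)
    g_min = min(g for *_, g in states)
    rt = params.rt
    n_bp = len(seq)
    z = 0.0
    pair = np.zeros((n_bp, n_bp))
    for occ, _, _, g in states:
        w = math.exp((g_min - g) / rt)
        z += w
        v = np.array(occ, dtype=float)
        pair += np.outer(v, v) * w
    return pair / z
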