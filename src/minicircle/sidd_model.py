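"""Two-state equilibrium model of supercoiling-induced strand separation.

Every base pair of a closed circle is either intact or separated; a
microstate is a set of at most ``r_max`` disjoint, non-adjacent circular
runs of separated base pairs totalling at most ``n_max`` bp.  Its free
energy (kcal/mol) is

    g = a_nuc * r  +  sum_{i open} b_i  +  Q(n, alpha)

with ``a_nuc`` the nucleation cost per run, ``b_i`` the copolymer
separation energy of base pair i (one value for A·T, one for G·C), and
``Q`` the torsional term obtained by minimising, over the uniform
interstrand helicity tau of the open regions,

    G_tor(tau) = (c_ss / 2) n tau^2
               + (K / 2) (alpha + n / A - n tau / 2 pi)^2 ,

where ``alpha`` is the linking difference (turns), ``A`` the helical
repeat unwound per separated bp, ``c_ss`` the interstrand twist stiffness
and ``K`` the quadratic residual-superhelicity coefficient (default
2200 R T / n_bp per turn^2).  The quadratic minimum is closed-form:

    Q(n, alpha) = K d^2 / (2 (1 + n K / (4 pi^2 c_ss))),   d = alpha + n/A
    Q(0, alpha) = K alpha^2 / 2 .

Boltzmann weights at ``temperature_K`` over the full restricted ensemble
give per-base-pair opening probabilities (raw, and max-normalised per
circle, matching the convention that relative — not absolute — opening
probabilities are compared between minicircles) and two-site joint
opening probabilities.  Bending stress is deliberately absent: the model
sees only topology and base-pairing thermodynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .sequences import CircularSequence

R_KCAL = 1.987204259e-3  # gas constant, kcal / (mol K)

Run = tuple[int, int]  # (0-based start, length), circular


@dataclass(frozen=True)
class EnergyParams:
    """Energy constants of the two-state model (kcal/mol unless noted).

    Defaults are literature-informed values for 300 K, 0.1 M monovalent
    salt; none are fitted here.  ``k_res_coeff`` and ``n_max`` default to
    ``None`` meaning "resolve from the circle size" (2200 R T / n_bp per
    turn^2 and min(n_bp - 2, 50) respectively).
    """

    a_nuc: float = 10.8
    b_at: float = 0.55
    b_gc: float = 1.35
    helicity_A: float = 10.4  # bp unwound per separated bp, in turns^-1 terms
    c_ss: float = 2.9  # kcal/mol rad^-2 per open bp
    k_res_coeff: float | None = None  # kcal/mol per turn^2
    temperature_K: float = 300.0
    r_max: int = 2
    n_max: int | None = None

    def __post_init__(self) -> None:
        if self.a_nuc <= 0:
            raise ValueError(f"a_nuc must be positive, got {self.a_nuc}")
        if not 0 < self.b_at < self.b_gc:
            raise ValueError(
                f"need 0 < b_at < b_gc, got b_at={self.b_at}, b_gc={self.b_gc}"
            )
        if self.helicity_A <= 0:
            raise ValueError(f"helicity_A must be positive, got {self.helicity_A}")
        if self.c_ss <= 0:
            raise ValueError(f"c_ss must be positive, got {self.c_ss}")
        if self.k_res_coeff is not None and self.k_res_coeff <= 0:
            raise ValueError(f"k_res_coeff must be positive, got {self.k_res_coeff}")
        if self.temperature_K <= 0:
            raise ValueError(
                f"temperature_K must be positive, got {self.temperature_K}"
            )
        if self.r_max < 1:
            raise ValueError(f"r_max must be >= 1, got {self.r_max}")
        if self.n_max is not None and self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature_K

    def k_res(self, n_bp: int) -> float:
        """Residual-superhelicity coefficient for an n_bp circle."""
        if self.k_res_coeff is not None:
            return self.k_res_coeff
        return 2200.0 * R_KCAL * self.temperature_K / n_bp

    def resolved_n_max(self, n_bp: int) -> int:
        n_max = self.n_max if self.n_max is not None else min(n_bp - 2, 50)
        if n_max >= n_bp - 1:
            raise ValueError(
                f"n_max={n_max} too large for a {n_bp}-bp circle: a circle "
                "must keep at least one closed bp per run boundary pair "
                f"(require n_max <= {n_bp - 2})"
            )
        return n_max

    def b_per_bp(self, seq: CircularSequence, dtype=np.float64) -> np.ndarray:
        """Per-position separation energies (copolymer energetics)."""
        at = seq.at_mask()
        return np.where(at, dtype(self.b_at), dtype(self.b_gc)).astype(dtype)


@dataclass(frozen=True)
class DenaturationState:
    """Disjoint non-adjacent open runs on a circle, with free energy."""

    runs: tuple[Run, ...]
    g: float = math.nan

    @property
    def r(self) -> int:
        return len(self.runs)

    @property
    def n(self) -> int:
        return sum(length for _, length in self.runs)

    def open_positions(self, n_bp: int) -> np.ndarray:
        """0-based open positions on an n_bp circle."""
        idx = [
            (s + k) % n_bp for s, length in self.runs for k in range(length)
        ]
        return np.array(sorted(idx), dtype=int)


@dataclass(frozen=True)
class DenaturationProfile:
    """Per-base-pair equilibrium opening probabilities for one circle."""

    p_raw: np.ndarray
    p_norm: np.ndarray
    mean_open_n: float
    log_z: float
    class_mass: tuple[float, ...]  # probability of r = 0, 1, ..., r_max

    @property
    def n_bp(self) -> int:
        return self.p_raw.size

    @property
    def z(self) -> float:
        return math.exp(self.log_z)

    def argmax_position(self) -> int:
        """1-based position of the most probable opening site (ties: lowest)."""
        return int(np.argmax(self.p_raw)) + 1


@dataclass(frozen=True)
class JointProfile:
    """log joint opening probability for every base-pair pair.

    Entries are natural logs; pairs never simultaneously open carry NaN
    as the "unsampled" sentinel (written as "NA" in text output).
    """

    log_p: np.ndarray

    @property
    def n_bp(self) -> int:
        return self.log_p.shape[0]


def _validate_runs(runs: Sequence[Run], n_bp: int) -> None:
    """Check runs are disjoint circular arcs separated by >= 1 closed bp."""
    if not runs:
        return
    occ = np.zeros(n_bp, dtype=bool)
    total = 0
    for s, length in runs:
        if length < 1 or length > n_bp - 1:
            raise ValueError(f"invalid run length {length} on a {n_bp}-bp circle")
        for k in range(length):
            occ[(s + k) % n_bp] = True
        total += length
    if int(occ.sum()) != total:
        raise ValueError("runs overlap")
    # maximal-run count must equal the declared run count, else two runs
    # touch and are really one (no closed bp between them)
    boundaries = int(np.sum(occ & ~np.roll(occ, 1)))
    if boundaries != len(runs):
        raise ValueError("runs are adjacent: need >= 1 closed bp between runs")


def torsional_energy(n: int, alpha: float, n_bp: int, params: EnergyParams) -> float:
    """Q(n, alpha): torsional free energy after analytic tau minimisation."""
    K = params.k_res(n_bp)
    if n == 0:
        return 0.5 * K * alpha * alpha
    d = alpha + n / params.helicity_A
    denom = 1.0 + n * K / (4.0 * math.pi**2 * params.c_ss)
    return 0.5 * K * d * d / denom


def _torsional_vector(n_max: int, alpha, n_bp: int, params: EnergyParams, dtype):
    """Q(n, alpha) for n = 0..n_max as an array of ``dtype``."""
    K = dtype(params.k_res(n_bp))
    n = np.arange(0, n_max + 1, dtype=dtype)
    d = dtype(alpha) + n / dtype(params.helicity_A)
    denom = dtype(1.0) + n * K / (dtype(4.0) * dtype(math.pi) ** 2 * dtype(params.c_ss))
    q = dtype(0.5) * K * d * d / denom
    q[0] = dtype(0.5) * K * dtype(alpha) ** 2
    return q


def state_energy(
    state: DenaturationState | Sequence[Run],
    seq: CircularSequence,
    alpha: float,
    params: EnergyParams | None = None,
) -> float:
    """Free energy (kcal/mol) of a denaturation state at linking difference alpha."""
    params = params or EnergyParams()
    runs = state.runs if isinstance(state, DenaturationState) else tuple(state)
    n_bp = len(seq)
    _validate_runs(runs, n_bp)
    b = params.b_per_bp(seq)
    n = sum(length for _, length in runs)
    sep = 0.0
    for s, length in runs:
        for k in range(length):
            sep += b[(s + k) % n_bp]
    return params.a_nuc * len(runs) + sep + torsional_energy(n, alpha, n_bp, params)


# ---------------------------------------------------------------------------
# state enumeration (general r_max; used for joint profiles, small circles,
# and as the slow path cross-checked against the vectorised r <= 2 path)
# ---------------------------------------------------------------------------


def _linear_placements(
    lo: int, hi: int, r_left: int, n_left: int
) -> Iterator[list[Run]]:
    """Non-adjacent runs inside linear positions [lo, hi], sorted by start."""
    yield []
    if r_left == 0 or n_left == 0 or lo > hi:
        return
    for s in range(lo, hi + 1):
        max_len = min(n_left, hi - s + 1)
        for length in range(1, max_len + 1):
            for rest in _linear_placements(s + length + 1, hi, r_left - 1, n_left - length):
                yield [(s, length)] + rest


def enumerate_states(n_bp: int, r_max: int, n_max: int) -> Iterator[tuple[Run, ...]]:
    """All states with 0 < r <= r_max runs and total open bp <= n_max.

    Each state appears exactly once.  The intact state is *not* yielded.
    Enumeration splits on whether position 0 is closed (all runs then lie
    in the linear segment 1..n_bp-1) or open (exactly one run wraps
    through 0, parameterised by its left/right extents).
    """
    if n_max > n_bp - 2:
        raise ValueError(f"n_max={n_max} must be <= n_bp - 2 = {n_bp - 2}")
    # position 0 closed
    for placement in _linear_placements(1, n_bp - 1, r_max, n_max):
        if placement:
            yield tuple(placement)
    # position 0 open: run covering 0 extends l1 bp left, l2 bp right
    for l2 in range(0, n_max):
        for l1 in range(0, n_max - l2):
            length0 = l1 + l2 + 1
            lo, hi = l2 + 2, n_bp - l1 - 2
            run0: Run = ((n_bp - l1) % n_bp, length0)
            for rest in _linear_placements(lo, hi, r_max - 1, n_max - length0):
                yield (run0, *rest)


def _profile_by_enumeration(
    seq: CircularSequence, alpha: float, params: EnergyParams, dtype
) -> DenaturationProfile:
    """Reference-path profile via explicit state enumeration (any r_max)."""
    n_bp = len(seq)
    n_max = params.resolved_n_max(n_bp)
    rt = params.rt
    b = params.b_per_bp(seq, dtype=np.float64)
    states = []
    g_min = torsional_energy(0, alpha, n_bp, params)
    for runs in enumerate_states(n_bp, params.r_max, n_max):
        n = sum(length for _, length in runs)
        sep = sum(
            b[(s + k) % n_bp] for s, length in runs for k in range(length)
        )
        g = params.a_nuc * len(runs) + sep + torsional_energy(n, alpha, n_bp, params)
        states.append((runs, g))
        g_min = min(g_min, g)
    g_intact = torsional_energy(0, alpha, n_bp, params)
    z = dtype(math.exp((g_min - g_intact) / rt))
    m = np.zeros(n_bp, dtype=dtype)
    class_z = np.zeros(params.r_max + 1, dtype=dtype)
    class_z[0] = z
    for runs, g in states:
        w = dtype(math.exp((g_min - g) / rt))
        z = z + w
        class_z[len(runs)] += w
        for s, length in runs:
            for k in range(length):
                m[(s + k) % n_bp] += w
    p_raw = (m / z).astype(dtype)
    return _finish_profile(p_raw, z, g_min, rt, class_z)


def _finish_profile(p_raw, z_shifted, g_shift, rt, class_z) -> DenaturationProfile:
    pmax = p_raw.max()
    p_norm = p_raw / pmax if pmax > 0 else np.zeros_like(p_raw)
    log_z = float(np.log(z_shifted)) - float(g_shift) / float(rt)
    return DenaturationProfile(
        p_raw=p_raw,
        p_norm=p_norm,
        mean_open_n=float(p_raw.sum()),
        log_z=log_z,
        class_mass=tuple(float(c / z_shifted) for c in class_z),
    )


def _run_energy_grid(b: np.ndarray, n_max: int, dtype) -> np.ndarray:
    """B[L-1, s] = separation energy of the circular run (s, L)."""
    n_bp = b.size
    doubled = np.concatenate([b, b]).astype(dtype)
    pref = np.concatenate([[dtype(0)], np.cumsum(doubled)])
    grid = np.empty((n_max, n_bp), dtype=dtype)
    for L in range(1, n_max + 1):
        grid[L - 1] = pref[L : L + n_bp] - pref[0:n_bp]
    return grid


def _spread_over_windows(weights: np.ndarray, length: int) -> np.ndarray:
    """Accumulate weights[s] onto circular positions s..s+length-1."""
    n_bp = weights.size
    edges = np.zeros(2 * n_bp + 1, dtype=weights.dtype)
    edges[:n_bp] += weights
    edges[length : length + n_bp] -= weights
    cum = np.cumsum(edges[:-1])
    return cum[:n_bp] + cum[n_bp:]


def denaturation_profile(
    seq: CircularSequence,
    alpha: float,
    params: EnergyParams | None = None,
    dtype=np.float64,
) -> DenaturationProfile:
    """Equilibrium per-base-pair opening probabilities of a circle.

    Enumerates every state with at most ``params.r_max`` open runs and at
    most ``params.n_max`` open base pairs (the intact state always
    included), Boltzmann-weights them at ``params.temperature_K`` and
    returns the per-position marginals, raw and per-circle max-normalised.

    ``dtype`` selects the accumulation precision; ``np.longdouble`` can be
    used when near-degenerate sequences must be resolved below float64
    summation noise.
    """
    params = params or EnergyParams()
    n_bp = len(seq)
    n_max = params.resolved_n_max(n_bp)
    if params.r_max > 2:
        return _profile_by_enumeration(seq, alpha, params, dtype)

    rt = dtype(params.rt)
    a = dtype(params.a_nuc)
    b = params.b_per_bp(seq, dtype=dtype)
    q = _torsional_vector(n_max, alpha, n_bp, params, dtype)
    g_intact = dtype(0.5) * dtype(params.k_res(n_bp)) * dtype(alpha) ** 2

    b_grid = _run_energy_grid(b, n_max, dtype)  # (n_max, n_bp)
    g1 = a + b_grid + q[1:, None]

    # lower bound on the minimum state energy -> exp arguments <= 0-ish
    g_shift = min(float(g_intact), float(g1.min()))
    if params.r_max >= 2 and n_max >= 2:
        b_min = b_grid.min(axis=1)
        for L1 in range(1, n_max):
            for L2 in range(1, n_max - L1 + 1):
                if n_bp - L1 - L2 - 1 < 1:
                    continue
                lb = float(2 * a + b_min[L1 - 1] + b_min[L2 - 1] + q[L1 + L2])
                g_shift = min(g_shift, lb)
    g_shift_d = dtype(g_shift)

    w_intact = np.exp((g_shift_d - g_intact) / rt)
    w1 = np.exp((g_shift_d - g1) / rt)
    z1 = w1.sum(dtype=dtype)
    marg = np.zeros(n_bp, dtype=dtype)
    for L in range(1, n_max + 1):
        marg += _spread_over_windows(w1[L - 1], L)

    z2 = dtype(0)
    class_z = np.zeros(params.r_max + 1, dtype=dtype)
    if params.r_max >= 2 and n_max >= 2:
        # per-run factors exp(-(a + B)/rt); the shift enters once per state
        w_run = np.exp(-(a + b_grid) / rt)
        run_cums = {}
        for L in range(1, n_max + 1):
            doubled = np.concatenate([w_run[L - 1], w_run[L - 1]])
            run_cums[L] = np.concatenate([[dtype(0)], np.cumsum(doubled)])
        ordered_total = dtype(0)
        for L1 in range(1, n_max):
            v_acc = np.zeros(n_bp, dtype=dtype)
            for L2 in range(1, n_max - L1 + 1):
                gap_total = n_bp - L1 - L2 - 1
                if gap_total < 1:
                    continue
                cum2 = run_cums[L2]
                lo = L1 + 1
                s_sum = cum2[lo + gap_total : lo + gap_total + n_bp] - cum2[lo : lo + n_bp]
                pref = np.exp((g_shift_d - q[L1 + L2]) / rt)
                v = w_run[L1 - 1] * s_sum * pref
                ordered_total += v.sum(dtype=dtype)
                v_acc += v
            marg += _spread_over_windows(v_acc, L1)
        z2 = ordered_total / dtype(2)

    z = w_intact + z1 + z2
    class_z[0] = w_intact
    class_z[1] = z1
    if params.r_max >= 2:
        class_z[2] = z2
    p_raw = marg / z
    return _finish_profile(p_raw, z, g_shift, float(rt), class_z)


def joint_profile(
    seq: CircularSequence,
    alpha: float,
    params: EnergyParams | None = None,
) -> JointProfile:
    """log joint probability that two base pairs are simultaneously open.

    Computed from the same restricted ensemble as
    :func:`denaturation_profile` by explicit state enumeration, so cost
    grows with the state count; intended for small circles or reduced
    ``n_max``.  Pairs that are never co-open in any enumerated state get
    the NaN sentinel.
    """
    params = params or EnergyParams()
    n_bp = len(seq)
    n_max = params.resolved_n_max(n_bp)
    rt = params.rt
    b = params.b_per_bp(seq)
    states = []
    g_min = torsional_energy(0, alpha, n_bp, params)
    for runs in enumerate_states(n_bp, params.r_max, n_max):
        n = sum(length for _, length in runs)
        sep = sum(b[(s + k) % n_bp] for s, length in runs for k in range(length))
        g = params.a_nuc * len(runs) + sep + torsional_energy(n, alpha, n_bp, params)
        states.append((runs, g))
        g_min = min(g_min, g)
    z = math.exp((g_min - torsional_energy(0, alpha, n_bp, params)) / rt)
    pair = np.zeros((n_bp, n_bp), dtype=np.float64)
    for runs, g in states:
        w = math.exp((g_min - g) / rt)
        z += w
        idx = np.array(
            [(s + k) % n_bp for s, length in runs for k in range(length)], dtype=int
        )
        pair[np.ix_(idx, idx)] += w
    p2 = pair / z
    with np.errstate(divide="ignore"):
        log_p = np.where(p2 > 0, np.log(np.where(p2 > 0, p2, 1.0)), np.nan)
    return JointProfile(log_p=log_p)


def ensemble_summary(profile: DenaturationProfile) -> dict:
    """Scalar summaries: mean open bp, run-class masses, profile entropy."""
    total = profile.p_raw.sum()
    if total > 0:
        q = profile.p_raw / total
        nz = q[q > 0]
        entropy = float(-(nz * np.log(nz)).sum())
    else:
        entropy = 0.0
    out = {
        "mean_open_bp": float(profile.mean_open_n),
        "profile_entropy_nats": entropy,
    }
    for r, mass in enumerate(profile.class_mass):
        out[f"p_r{r}"] = float(mass)
    return out
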