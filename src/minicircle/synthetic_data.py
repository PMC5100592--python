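"""Seeded generators emulating the simulation outputs the analysis consumes.

Nothing here reproduces a physical engine: the point is statistical
structure.  The open/close generator runs single-base-pair-flip
Metropolis dynamics on the two-state equilibrium energy of
:mod:`minicircle.sidd_model` (restricted to ``r <= r_max`` open runs), so
its long-run per-base-pair marginals converge to the model profile; an
optional antipodal coupling term lowers the energy of two-run states
whose run centres sit at opposite sides of the circle, emulating the
cooperative kinking seen in bent minicircles.  Breathing series are
independent two-state telegraph processes with sequence-dependent rates
(base pairs flanking CA/TA/CG/AT steps open faster).  Helical-parameter
samples are Gaussian draws from a stiffness library, suitable for
stiffness-recovery tests.

All generators are pure functions of (config, seed): a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elasticity import StepStiffness
from .sequences import BREATHING_PRONE_STEPS, YPR_STEPS, CircularSequence
from .sidd_model import EnergyParams
from .trajectory_analysis import (
    KIND_BOOL,
    KIND_DISTANCE,
    BasePairTrajectory,
)

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the equilibrium open/close trajectory generator.

    ``antipodal_coupling_kcal`` is the energy bonus (kcal/mol) granted to
    two-run states whose run centres are antipodal within
    ``antipodal_band_halfwidth_bp``; zero disables the coupling.  Distance
    emission draws closed base pairs around ``closed_mean_A`` and open
    ones around ``open_mean_A`` (both with ``emission_spread_A``), chosen
    well clear of the 4 A open-call threshold.
    """

    seed: int = 0
    n_bp: int = 24
    n_frames: int = 1000
    dt_ns: float = 0.1
    alpha: float = -1.0
    energy_params: EnergyParams = field(default_factory=EnergyParams)
    sequence: CircularSequence | None = None
    flip_attempt_rate: float = 1.0  # attempted flips per bp per frame
    antipodal_coupling_kcal: float = 0.0
    antipodal_band_halfwidth_bp: int = 2
    burn_in_frames: int = 100
    emit: str = "bool"  # "bool" or "distance"
    closed_mean_A: float = 2.0
    open_mean_A: float = 6.0
    emission_spread_A: float = 0.5

    def __post_init__(self) -> None:
        if self.n_bp < 3:
            raise ValueError(f"n_bp must be >= 3, got {self.n_bp}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.dt_ns <= 0:
            raise ValueError(f"dt_ns must be positive, got {self.dt_ns}")
        if self.flip_attempt_rate < 0:
            raise ValueError("flip_attempt_rate must be >= 0")
        if self.antipodal_coupling_kcal < 0:
            raise ValueError("antipodal_coupling_kcal must be >= 0")
        if self.burn_in_frames < 0:
            raise ValueError("burn_in_frames must be >= 0")
        if self.emit not in ("bool", "distance"):
            raise ValueError(f"emit must be 'bool' or 'distance', got {self.emit!r}")
        if self.open_mean_A <= self.closed_mean_A:
            raise ValueError("open_mean_A must exceed closed_mean_A")
        if self.emission_spread_A <= 0:
            raise ValueError("emission_spread_A must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_bp:
            raise ValueError(
                f"sequence length {len(self.sequence)} != n_bp {self.n_bp}"
            )

    def resolved_sequence(self) -> CircularSequence:
        if self.sequence is not None:
            return self.sequence
        return CircularSequence("AT" * (self.n_bp // 2) + "A" * (self.n_bp % 2),
                                name="generator_default")


def _runs_from_occupancy(occ: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, length)."""
    n = occ.size
    if not occ.any():
        return []
    if occ.all():
        return [(0, n)]
    starts = np.flatnonzero(occ & ~np.roll(occ, 1))
    runs = []
    for s in starts:
        length = 0
        while occ[(s + length) % n]:
            length += 1
        runs.append((int(s), length))
    return runs


def _antipodal_bonus(occ: np.ndarray, coupling: float, halfwidth: int) -> float:
    """-coupling if the state has exactly two runs with antipodal centres."""
    runs = _runs_from_occupancy(occ)
    if len(runs) != 2:
        return 0.0
    n = occ.size
    centres = [(s + (length - 1) / 2.0) % n for s, length in runs]
    d = abs(centres[0] - centres[1])
    d = min(d, n - d)
    if abs(d - n / 2.0) <= halfwidth:
        return -coupling
    return 0.0


def generate_open_close_trajectory(cfg: GeneratorConfig) -> BasePairTrajectory:
    """Metropolis-sampled open/close trajectory on the equilibrium energy.

    Single-bp flips are proposed uniformly; moves that would exceed
    ``r_max`` runs or ``n_max`` open bp are rejected, so the chain samples
    exactly the restricted ensemble of the equilibrium model (plus the
    optional antipodal coupling).  One frame is recorded per sweep of
    ``flip_attempt_rate * n_bp`` attempts, after ``burn_in_frames``
    discarded sweeps.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = cfg.resolved_sequence()
    params = cfg.energy_params
    n_bp = cfg.n_bp
    n_max = params.resolved_n_max(n_bp)
    r_max = params.r_max
    rt = params.rt
    a_nuc = params.a_nuc
    b = params.b_per_bp(seq)
    k_res = params.k_res(n_bp)
    q_table = np.empty(n_max + 2)
    for n in range(n_max + 1):
        if n == 0:
            q_table[n] = 0.5 * k_res * cfg.alpha**2
        else:
            d = cfg.alpha + n / params.helicity_A
            denom = 1.0 + n * k_res / (4.0 * math.pi**2 * params.c_ss)
            q_table[n] = 0.5 * k_res * d * d / denom
    q_table[n_max + 1] = math.inf

    coupling = cfg.antipodal_coupling_kcal
    halfwidth = cfg.antipodal_band_halfwidth_bp

    occ = np.zeros(n_bp, dtype=bool)
    n_open, n_runs = 0, 0
    attempts_per_frame = int(round(cfg.flip_attempt_rate * n_bp))
    frames = np.zeros((cfg.n_frames, n_bp), dtype=bool)

    total_frames = cfg.burn_in_frames + cfg.n_frames
    for f in range(total_frames):
        if attempts_per_frame:
            sites = rng.integers(0, n_bp, size=attempts_per_frame)
            us = rng.random(attempts_per_frame)
            for i, u in zip(sites, us):
                left = occ[(i - 1) % n_bp]
                right = occ[(i + 1) % n_bp]
                if occ[i]:  # propose closing
                    new_n = n_open - 1
                    if left and right:
                        dr = 1  # splitting a run
                    elif left or right:
                        dr = 0
                    else:
                        dr = -1  # removing an isolated open bp
                    dg = -b[i]
                else:  # propose opening
                    new_n = n_open + 1
                    if new_n > n_max:
                        continue
                    if left and right:
                        dr = -1  # merging two runs
                    elif left or right:
                        dr = 0
                    else:
                        dr = 1  # nucleating a run
                    dg = b[i]
                new_r = n_runs + dr
                if new_r > r_max:
                    continue
                dg += a_nuc * dr + q_table[new_n] - q_table[n_open]
                if coupling > 0.0 and (n_runs == 2 or new_r == 2):
                    bonus_old = _antipodal_bonus(occ, coupling, halfwidth)
                    occ[i] = not occ[i]
                    bonus_new = _antipodal_bonus(occ, coupling, halfwidth)
                    occ[i] = not occ[i]
                    dg += bonus_new - bonus_old
                if dg <= 0.0 or u < math.exp(-dg / rt):
                    occ[i] = not occ[i]
                    n_open, n_runs = new_n, new_r
        if f >= cfg.burn_in_frames:
            frames[f - cfg.burn_in_frames] = occ

    if cfg.emit == "bool":
        return BasePairTrajectory(values=frames, dt_ns=cfg.dt_ns, kind=KIND_BOOL)
    noise = rng.normal(0.0, cfg.emission_spread_A, size=frames.shape)
    values = np.where(frames, cfg.open_mean_A, cfg.closed_mean_A) + noise
    return BasePairTrajectory(
        values=np.maximum(values, 0.0), dt_ns=cfg.dt_ns, kind=KIND_DISTANCE
    )


def default_breathing_rates(
    seq: CircularSequence,
    k_open_prone: float = 0.4,
    k_open_other: float = 0.02,
    k_close: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bp telegraph rates (ns^-1): faster opening next to soft steps.

    A base pair flanked by at least one CA/TA/CG/AT step gets
    ``k_open_prone``; others ``k_open_other``.  Closing is uniform and
    fast so open episodes stay in the breathing (sub-ns) regime.
    """
    n = len(seq)
    k_open = np.full(n, k_open_other)
    for pos in range(1, n + 1):
        flanks = (seq.step(pos - 1), seq.step(pos))
        if any(s in BREATHING_PRONE_STEPS for s in flanks):
            k_open[pos - 1] = k_open_prone
    return k_open, np.full(n, k_close)


def generate_breathing_series(
    cfg: GeneratorConfig,
    per_bp_rates: tuple[np.ndarray, np.ndarray] | None = None,
) -> BasePairTrajectory:
    """Independent two-state telegraph processes per base pair.

    Open/close transition probabilities per frame follow the exponential
    waiting-time discretisation ``1 - exp(-k dt)``; the initial state is
    drawn from the stationary occupancy ``k_open / (k_open + k_close)``.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = cfg.resolved_sequence()
    if per_bp_rates is None:
        k_open, k_close = default_breathing_rates(seq)
    else:
        k_open = np.asarray(per_bp_rates[0], dtype=float)
        k_close = np.asarray(per_bp_rates[1], dtype=float)
    if k_open.shape != (cfg.n_bp,) or k_close.shape != (cfg.n_bp,):
        raise ValueError("rate vectors must have one entry per base pair")
    if (k_open < 0).any() or (k_close < 0).any():
        raise ValueError("rates must be non-negative")

    with np.errstate(divide="ignore", invalid="ignore"):
        occupancy = np.where(
            k_open + k_close > 0, k_open / (k_open + k_close), 0.0
        )
    p_open = 1.0 - np.exp(-k_open * cfg.dt_ns)
    p_close = 1.0 - np.exp(-k_close * cfg.dt_ns)

    state = rng.random(cfg.n_bp) < occupancy
    frames = np.zeros((cfg.n_frames, cfg.n_bp), dtype=bool)
    for f in range(cfg.n_frames):
        u = rng.random(cfg.n_bp)
        state = np.where(state, u >= p_close, u < p_open)
        frames[f] = state
    return BasePairTrajectory(values=frames, dt_ns=cfg.dt_ns, kind=KIND_BOOL)


def generate_helical_samples(
    library: dict[str, StepStiffness],
    n_per_type: int,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Gaussian helical-parameter draws from a stiffness library.

    Returns per step type an (n_per_type, 6) array drawn from the
    library's mean and covariance, for stiffness-recovery exercises.
    """
    if n_per_type < 1:
        raise ValueError(f"n_per_type must be >= 1, got {n_per_type}")
    rng = np.random.default_rng(seed)
    out = {}
    for step_type in sorted(library):
        entry = library[step_type]
        out[step_type] = rng.multivariate_normal(
            entry.mean, entry.covariance, size=n_per_type
        )
    return out


def default_step_library(temperature_K: float = 300.0) -> dict[str, StepStiffness]:
    """Synthetic per-step-type stiffness library (not simulation-derived).

    A deterministic, plausible stand-in for a simulation-derived
    parameter table: translations in Angstrom, rotations in degrees.
    Pyrimidine-purine steps get larger angular fluctuations (they are the
    flexurally soft steps), AG/GA carry the extreme low/high equilibrium
    twists, and a mild slide-twist correlation keeps the covariances
    non-trivial.  Labelled synthetic; use real parameter tables for any
    quantitative sequence comparison.
    """
    twist_means = {
        "AA": 35.3, "AT": 31.2, "TA": 36.0, "TT": 35.3,
        "AC": 33.0, "CA": 34.5, "GT": 33.0, "TG": 34.5,
        "AG": 29.0, "GA": 42.0, "CT": 29.0, "TC": 42.0,
        "GC": 34.0, "CG": 35.5, "GG": 33.7, "CC": 33.7,
    }
    base_sd = np.array([0.55, 0.65, 0.30, 3.5, 4.5, 4.0])
    library = {}
    for d in DINUCLEOTIDES:
        sd = base_sd.copy()
        if d in YPR_STEPS:
            sd[3:] *= 1.35  # soft steps fluctuate more in tilt/roll/twist
        corr = np.eye(6)
        corr[1, 5] = corr[5, 1] = 0.25  # slide-twist
        corr[4, 5] = corr[5, 4] = -0.20  # roll-twist
        cov = corr * np.outer(sd, sd)
        mean = np.array([0.0, 0.2, 3.32, 0.0, 2.5, twist_means[d]])
        library[d] = StepStiffness(
            step_type=d, mean=mean, covariance=cov, temperature_K=temperature_K
        )
    return library


def synthetic_random_circle(
    n_bp: int = 106, at_fraction: float = 0.5, seed: int = 2016
) -> CircularSequence:
    """Synthetic stand-in for a mixed-content random minicircle sequence.

    Bases are drawn i.i.d. with A/T probability ``at_fraction`` split
    evenly, G/C likewise.  This is *not* any published sequence; it is a
    labelled synthetic surrogate with the same gross composition.
    """
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError(f"at_fraction must be in [0, 1], got {at_fraction}")
    rng = np.random.default_rng(seed)
    bases = rng.choice(
        list("ATGC"),
        size=n_bp,
        p=[at_fraction / 2, at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2],
    )
    return CircularSequence("".join(bases), name=f"RANDOM_synthetic_{seed}")


def synthetic_fuse_circle(
    n_bp: int = 106,
    seed: int = 2016,
    insert_span: tuple[int, int] = (1, 50),
    insert_at_fraction: float = 0.8,
) -> CircularSequence:
    """Synthetic AT-rich-insert circle emulating a FUSE-style embedding.

    Takes the synthetic random circle for ``seed`` and replaces the
    1-based positions ``insert_span`` (inclusive) with an AT-rich random
    stretch, mimicking the replacement of half a random minicircle by a
    denaturation-prone far-upstream-element segment.  Synthetic stand-in,
    not the published sequence.
    """
    lo, hi = insert_span
    if not (1 <= lo <= hi <= n_bp):
        raise ValueError(f"invalid insert span {insert_span} for {n_bp} bp")
    base = synthetic_random_circle(n_bp=n_bp, seed=seed)
    rng = np.random.default_rng(seed + 1)
    insert = rng.choice(
        list("ATGC"),
        size=hi - lo + 1,
        p=[
            insert_at_fraction / 2,
            insert_at_fraction / 2,
            (1 - insert_at_fraction) / 2,
            (1 - insert_at_fraction) / 2,
        ],
    )
    bases = list(base.bases)
    bases[lo - 1 : hi] = list(insert)
    return CircularSequence("".join(bases), name=f"FUSE_synthetic_{seed}")
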