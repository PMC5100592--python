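"""Trajectory-level denaturation statistics for circular DNA.

Works on per-frame, per-base-pair observables emitted by simulation
engines (or the packaged synthetic generators): hydrogen-bond distances
or energies are thresholded into open/closed calls, from which breathing
events, empirical denaturation profiles, mutual (two-site) denaturation
maps, antipodal-cooperativity statistics, defect classifications and
twist-deviation time series are derived.

Conventions pinned here:

* a base pair is *open* when its middle hydrogen-bond distance strictly
  exceeds 4 Angstrom, or its hydrogen-bond energy is less negative than
  -3.03e-21 J (10% of the effective well depth);
* a *breathing* event is a base pair that opens and recloses within 1 ns
  (open episodes touching a trajectory end cannot be verified to close
  and are never counted);
* a structural disruption is *persistent* once it lasts 10 ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sidd_model import JointProfile

KIND_DISTANCE = "hbond_distance_A"
KIND_ENERGY = "hbond_energy_J"
KIND_BOOL = "open_bool"

DEFECT_KINDS = ("intact", "breathing", "kink_I", "kink_II", "bubble", "wrinkle", "slip")


@dataclass(frozen=True)
class OpenCallConfig:
    """Thresholds for open-base classification and breathing windows."""

    distance_threshold_A: float = 4.0
    energy_threshold_J: float = -3.03e-21
    breathing_max_ns: float = 1.0

    def __post_init__(self) -> None:
        for name in ("distance_threshold_A", "energy_threshold_J", "breathing_max_ns"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.breathing_max_ns <= 0:
            raise ValueError(
                f"breathing_max_ns must be positive, got {self.breathing_max_ns}"
            )


@dataclass
class BasePairTrajectory:
    """Per-frame per-base-pair observable series on a circle.

    ``values`` is (n_frames, n_bp); ``kind`` states what the numbers are.
    Optional auxiliary channels share the frame axis: ``stacking_broken``
    marks steps whose stacking is lost (step i couples bp i and i+1,
    circularly) and ``registry_shift`` carries integer pairing-register
    offsets for slip detection.  ``step_twist_deg`` holds per-step twists.
    """

    values: np.ndarray
    dt_ns: float
    kind: str = KIND_DISTANCE
    stacking_broken: np.ndarray | None = None
    registry_shift: np.ndarray | None = None
    step_twist_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.dt_ns <= 0:
            raise ValueError(f"dt_ns must be positive, got {self.dt_ns}")
        if self.kind not in (KIND_DISTANCE, KIND_ENERGY, KIND_BOOL):
            raise ValueError(f"unknown observable kind {self.kind!r}")
        if self.kind == KIND_DISTANCE and (self.values < 0).any():
            raise ValueError("hydrogen-bond distances must be non-negative")
        for name in ("stacking_broken", "registry_shift", "step_twist_deg"):
            aux = getattr(self, name)
            if aux is not None and np.asarray(aux).shape != self.values.shape:
                raise ValueError(
                    f"{name} shape {np.asarray(aux).shape} does not match "
                    f"values shape {self.values.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bp(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DefectCall:
    """One classified structural episode."""

    kind: str
    span: tuple[int, int]  # (1-based start bp, length, circular)
    first_frame: int
    last_frame: int
    persistent: bool

    @property
    def duration_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


@dataclass(frozen=True)
class BreathingStats:
    per_bp: np.ndarray  # event count per base pair
    total: int
    rate_per_bp_per_ns: float


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no finite entries to average."""


def call_open(traj: BasePairTrajectory, cfg: OpenCallConfig | None = None) -> np.ndarray:
    """Boolean (n_frames, n_bp) open matrix from the trajectory observable.

    Distances: open iff value strictly exceeds the 4 A threshold.
    Energies: open iff value is greater (less negative) than the
    -3.03e-21 J threshold.  Boolean input passes through.
    """
    cfg = cfg or OpenCallConfig()
    if traj.kind == KIND_DISTANCE:
        return traj.values > cfg.distance_threshold_A
    if traj.kind == KIND_ENERGY:
        return traj.values > cfg.energy_threshold_J
    if traj.kind == KIND_BOOL:
        return traj.values.astype(bool)
    raise ValueError(f"no threshold rule for observable kind {traj.kind!r}")


def _open_runs_1d(col: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_frame, last_frame), inclusive."""
    padded = np.concatenate([[False], col, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def breathing_events(
    open_matrix: np.ndarray,
    dt_ns: float,
    cfg: OpenCallConfig | None = None,
) -> BreathingStats:
    """Count reversible breathing events per base pair.

    A breathing event is a maximal run of consecutive open frames bounded
    by closed frames on both sides whose open duration (run length x
    ``dt_ns``) does not exceed ``breathing_max_ns``.  Runs touching either
    trajectory end are not counted (closure unverifiable); longer bounded
    episodes count as disruptions, not breathing.
    """
    cfg = cfg or OpenCallConfig()
    open_matrix = np.asarray(open_matrix, dtype=bool)
    if dt_ns <= 0:
        raise ValueError(f"dt_ns must be positive, got {dt_ns}")
    if dt_ns > cfg.breathing_max_ns:
        raise ValueError(
            f"frame spacing {dt_ns} ns cannot resolve breathing events "
            f"shorter than {cfg.breathing_max_ns} ns"
        )
    n_frames, n_bp = open_matrix.shape
    counts = np.zeros(n_bp, dtype=int)
    for j in range(n_bp):
        for first, last in _open_runs_1d(open_matrix[:, j]):
            if first == 0 or last == n_frames - 1:
                continue  # episode touches a trajectory end
            if (last - first + 1) * dt_ns <= cfg.breathing_max_ns:
                counts[j] += 1
    total = int(counts.sum())
    duration_ns = n_frames * dt_ns
    return BreathingStats(
        per_bp=counts,
        total=total,
        rate_per_bp_per_ns=total / (n_bp * duration_ns),
    )


def denaturation_probability(open_matrices) -> np.ndarray:
    """Per-base-pair open fraction, pooling replicates frame-weighted.

    Accepts one boolean matrix or a sequence of matrices with equal bp
    counts; pooling weights every frame equally, so replicates of unequal
    length contribute in proportion to their frames.
    """
    if isinstance(open_matrices, np.ndarray) and open_matrices.ndim == 2:
        open_matrices = [open_matrices]
    mats = [np.asarray(m, dtype=bool) for m in open_matrices]
    if not mats:
        raise ValueError("at least one open matrix is required")
    n_bp = mats[0].shape[1]
    for m in mats:
        if m.shape[1] != n_bp:
            raise ValueError("replicates disagree on the number of base pairs")
    stacked = np.vstack(mats)
    if stacked.shape[0] < 1:
        raise ValueError("at least one frame is required")
    return stacked.mean(axis=0)


def replicate_error_bars(open_matrices) -> np.ndarray:
    """Per-bp standard deviation of the open fraction across replicates."""
    profs = np.stack(
        [np.asarray(m, dtype=bool).mean(axis=0) for m in open_matrices]
    )
    return profs.std(axis=0, ddof=1)


def mutual_denaturation_map(open_matrix: np.ndarray) -> JointProfile:
    """log fraction of frames in which each base-pair pair is co-open.

    Never co-open pairs carry the NaN ("unsampled") sentinel; the
    diagonal is the log of the single-site open fraction.
    """
    o = np.asarray(open_matrix, dtype=float)
    if o.ndim != 2 or o.shape[0] < 1:
        raise ValueError("open matrix must be (n_frames >= 1, n_bp)")
    co = (o.T @ o) / o.shape[0]
    with np.errstate(divide="ignore"):
        log_p = np.where(co > 0, np.log(np.where(co > 0, co, 1.0)), np.nan)
    return JointProfile(log_p=log_p)


def circular_separation(n_bp: int) -> np.ndarray:
    """Matrix of circular index separations min(|i-j|, N-|i-j|)."""
    idx = np.arange(n_bp)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n_bp - d)


def antipodal_enhancement(joint: JointProfile, band_halfwidth_bp: int) -> float:
    """Antipodal excess of the mutual denaturation map.

    Mean finite log joint probability over off-diagonal pairs whose
    circular separation lies within ``band_halfwidth_bp`` of N/2, minus
    the mean over all other off-diagonal finite pairs.  Positive values
    indicate cooperative opening at opposite sides of the circle.
    """
    n_bp = joint.n_bp
    if n_bp < 2 * band_halfwidth_bp:
        raise ValueError(
            f"band halfwidth {band_halfwidth_bp} too large for {n_bp} bp"
        )
    sep = circular_separation(n_bp)
    off_diag = sep > 0
    band = off_diag & (np.abs(sep - n_bp / 2.0) <= band_halfwidth_bp)
    rest = off_diag & ~band
    vals_band = joint.log_p[band]
    vals_rest = joint.log_p[rest]
    vals_band = vals_band[np.isfinite(vals_band)]
    vals_rest = vals_rest[np.isfinite(vals_rest)]
    if vals_band.size == 0:
        raise UndefinedStatisticError(
            "no finite mutual-denaturation entries in the antipodal band"
        )
    if vals_rest.size == 0:
        raise UndefinedStatisticError(
            "no finite mutual-denaturation entries outside the antipodal band"
        )
    return float(vals_band.mean() - vals_rest.mean())


def antipodal_permutation_null(
    open_matrix: np.ndarray,
    band_halfwidth_bp: int,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the antipodal statistic under bp-label shuffles.

    Randomly permuting base-pair labels destroys the circular geometry
    while preserving the per-pair co-opening values, giving a null for
    "no relationship between separation and co-opening".  Permutations in
    which the statistic is undefined are skipped.
    """
    rng = rng or np.random.default_rng()
    o = np.asarray(open_matrix, dtype=bool)
    null = []
    for _ in range(n_permutations):
        perm = rng.permutation(o.shape[1])
        try:
            null.append(
                antipodal_enhancement(
                    mutual_denaturation_map(o[:, perm]), band_halfwidth_bp
                )
            )
        except UndefinedStatisticError:
            continue
    if not null:
        raise UndefinedStatisticError("antipodal statistic undefined in all permutations")
    return np.array(null)


def _circular_components(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """4-connected components of a (frames, bp) mask, circular in bp.

    Returns (frame_indices, bp_indices) per component.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n_lab = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_lab == 0:
        return []
    # merge labels that touch across the bp wrap (columns 0 and N-1)
    parent = list(range(n_lab + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    if mask.shape[1] > 1:
        left, right = labels[:, 0], labels[:, -1]
        for la, lb in zip(left, right):
            if la and lb:
                union(int(la), int(lb))
    groups: dict[int, list[int]] = {}
    for lab in range(1, n_lab + 1):
        groups.setdefault(find(lab), []).append(lab)
    out = []
    for members in groups.values():
        sel = np.isin(labels, members)
        ff, bb = np.nonzero(sel)
        out.append((ff, bb))
    return out


def _circular_span(bp_indices: np.ndarray, n_bp: int) -> tuple[int, int]:
    """(1-based start, length) of the minimal circular arc covering indices."""
    uniq = np.unique(bp_indices)
    width = uniq.size
    if width == n_bp:
        return (1, n_bp)
    present = np.zeros(n_bp, dtype=bool)
    present[uniq] = True
    # longest run of absent positions; span starts just after it
    best_len, best_end, cur = 0, -1, 0
    for i in range(2 * n_bp):
        if not present[i % n_bp]:
            cur += 1
            if cur > best_len:
                best_len, best_end = cur, i
        else:
            cur = 0
        if cur >= n_bp:
            break
    start = (best_end + 1) % n_bp
    return (start + 1, n_bp - best_len)


def classify_defects(
    traj: BasePairTrajectory,
    cfg: OpenCallConfig | None = None,
    persistence_ns: float = 10.0,
) -> list[DefectCall]:
    """Classify structural episodes into the defect taxonomy.

    Broken-pairing episodes (connected regions of open base pairs in the
    frame x bp grid, circular in bp) are labelled by width and duration:

    * width 1, duration <= breathing window  -> ``breathing``
    * duration >= ``persistence_ns``, width >= 2 -> ``bubble``
    * duration >= ``persistence_ns``, width 1   -> ``kink_II``
    * anything shorter                          -> ``wrinkle``

    Type I kinks (stacking broken, all pairing intact) require the
    ``stacking_broken`` channel; slip defects (sustained non-zero pairing
    register) require ``registry_shift``.  Missing channels produce a
    warning and those kinds are skipped.
    """
    cfg = cfg or OpenCallConfig()
    if persistence_ns <= 0:
        raise ValueError(f"persistence_ns must be positive, got {persistence_ns}")
    open_matrix = call_open(traj, cfg)
    dt = traj.dt_ns
    calls: list[DefectCall] = []

    for ff, bb in _circular_components(open_matrix):
        duration = (ff.max() - ff.min() + 1) * dt
        width = np.unique(bb).size
        persistent = duration >= persistence_ns
        if width == 1 and duration <= cfg.breathing_max_ns:
            kind = "breathing"
        elif persistent:
            kind = "bubble" if width >= 2 else "kink_II"
        else:
            kind = "wrinkle"
        calls.append(
            DefectCall(
                kind=kind,
                span=_circular_span(bb, traj.n_bp),
                first_frame=int(ff.min()),
                last_frame=int(ff.max()),
                persistent=bool(persistent),
            )
        )

    if traj.stacking_broken is None:
        warnings.warn("no stacking channel: skipping kink_I calls", stacklevel=2)
    else:
        stack = np.asarray(traj.stacking_broken, dtype=bool)
        n_bp = traj.n_bp
        # step j pairs bp j and j+1 (circular); kink_I needs both intact
        pairing_intact = ~open_matrix & ~np.roll(open_matrix, -1, axis=1)
        kink1_mask = stack & pairing_intact
        for ff, bb in _circular_components(kink1_mask):
            duration = (ff.max() - ff.min() + 1) * dt
            if duration < persistence_ns:
                continue
            calls.append(
                DefectCall(
                    kind="kink_I",
                    span=_circular_span(bb, n_bp),
                    first_frame=int(ff.min()),
                    last_frame=int(ff.max()),
                    persistent=True,
                )
            )

    if traj.registry_shift is None:
        warnings.warn("no pairing-registry channel: skipping slip calls", stacklevel=2)
    else:
        reg = np.asarray(traj.registry_shift)
        for ff, bb in _circular_components(np.abs(reg) >= 1):
            duration = (ff.max() - ff.min() + 1) * dt
            if duration < persistence_ns:
                continue
            calls.append(
                DefectCall(
                    kind="slip",
                    span=_circular_span(bb, traj.n_bp),
                    first_frame=int(ff.min()),
                    last_frame=int(ff.max()),
                    persistent=True,
                )
            )
    return calls


def twist_deviation_series(
    step_twist_deg: np.ndarray, reference_twists_deg
) -> np.ndarray:
    """Per-frame mean deviation of step twists from their reference values.

    ``reference_twists_deg`` may be a scalar or a per-step vector; the
    mean is taken over steps within each frame, so a relaxing circle shows
    the series trending toward zero.
    """
    twists = np.asarray(step_twist_deg, dtype=float)
    ref = np.asarray(reference_twists_deg, dtype=float)
    if ref.ndim == 1 and ref.size != twists.shape[1]:
        raise ValueError(
            f"reference vector length {ref.size} does not match "
            f"{twists.shape[1]} steps"
        )
    return (twists - ref).mean(axis=1)
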