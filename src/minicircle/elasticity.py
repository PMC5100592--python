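"""Base-pair-step stiffness matrices and harmonic elastic energies.

Each step of a duplex is described by six rigid-body parameters, ordered
package-wide as (shift, slide, rise, tilt, roll, twist) -- translations
in Angstrom, rotations in degrees.  From fluctuations sampled around the
equilibrium geometry of a given step type, the stiffness matrix is

    A = kB T C^{-1}

with C the (unbiased) sample covariance of the six parameters.  The
elastic energy of a deformed step is the quadratic form

    E = 1/2 sum_ij a_ij dp_i dp_j

with dp the deviation from the step-type mean.  Summing over the steps
of a minicircle gives the stored harmonic energy; the pure-twist diagonal
contribution is reported separately because torsional stress dominates
the differences between supercoiled topoisomers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KB_KCAL = 1.987204259e-3  # Boltzmann constant x Avogadro, kcal/(mol K)

PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
TWIST_INDEX = 5


@dataclass(frozen=True)
class StepStiffness:
    """Equilibrium geometry and stiffness of one base-pair-step type.

    ``covariance`` is the 6x6 parameter covariance C; ``stiffness`` (a
    property) is A = kB T C^{-1} in kcal/mol per squared parameter unit,
    and ``stiffness_kt`` the same in units of kB T.
    """

    step_type: str
    mean: np.ndarray
    covariance: np.ndarray
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.shape != (6,):
            raise ValueError(f"mean must be a 6-vector, got shape {mean.shape}")
        if cov.shape != (6, 6):
            raise ValueError(f"covariance must be 6x6, got shape {cov.shape}")
        if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        _require_positive_definite(cov, context=f"step type {self.step_type!r}")
        if self.temperature_K <= 0:
            raise ValueError(f"temperature_K must be positive, got {self.temperature_K}")

    @property
    def stiffness_kt(self) -> np.ndarray:
        """C^{-1}: stiffness in kB T per squared parameter unit."""
        return np.linalg.inv(self.covariance)

    @property
    def stiffness(self) -> np.ndarray:
        """kB T C^{-1} in kcal/mol per squared parameter unit."""
        return KB_KCAL * self.temperature_K * self.stiffness_kt


def _require_positive_definite(cov: np.ndarray, context: str = "") -> None:
    eigvals, eigvecs = np.linalg.eigh(cov)
    tol = 1e-10 * max(abs(eigvals.max()), 1.0)
    if eigvals.min() <= tol:
        k = int(np.argmin(eigvals))
        direction = ", ".join(
            f"{name}={c:+.3f}" for name, c in zip(PARAM_NAMES, eigvecs[:, k])
        )
        where = f" ({context})" if context else ""
        raise ValueError(
            f"covariance is singular or indefinite{where}: null direction "
            f"[{direction}] with eigenvalue {eigvals[k]:.3e}"
        )


def stiffness_from_samples(
    samples: np.ndarray,
    temperature_K: float = 300.0,
    step_type: str = "NN",
) -> StepStiffness:
    """Estimate a step stiffness matrix from helical-parameter samples.

    ``samples`` is (n, 6) with n >= 7 so the unbiased covariance is
    invertible; a singular covariance raises an error naming the null
    direction.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 6:
        raise ValueError(f"samples must be (n, 6), got shape {samples.shape}")
    if samples.shape[0] < 7:
        raise ValueError(
            f"need >= 7 samples to estimate a 6x6 covariance, got {samples.shape[0]}"
        )
    if not np.isfinite(samples).all():
        raise ValueError("samples contain non-finite values")
    mean = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, ddof=1)
    return StepStiffness(
        step_type=step_type, mean=mean, covariance=cov, temperature_K=temperature_K
    )


def step_energy(delta_p: np.ndarray, stiffness: np.ndarray) -> float:
    """Harmonic energy 1/2 dp^T A dp of one deformed step.

    Units follow the stiffness matrix: pass ``StepStiffness.stiffness_kt``
    for kB T, ``.stiffness`` for kcal/mol.
    """
    dp = np.asarray(delta_p, dtype=float)
    a = np.asarray(stiffness, dtype=float)
    if dp.shape != (6,):
        raise ValueError(f"delta_p must be a 6-vector, got shape {dp.shape}")
    if a.shape != (6, 6):
        raise ValueError(f"stiffness must be 6x6, got shape {a.shape}")
    if not np.allclose(a, a.T, rtol=1e-8, atol=1e-12):
        raise ValueError("stiffness matrix must be symmetric")
    return float(0.5 * dp @ a @ dp)


def circle_elastic_energy(
    structure: np.ndarray,
    step_types: list[str],
    library: dict[str, StepStiffness],
) -> dict:
    """Harmonic elastic energy of a circle structure against a library.

    ``structure`` is (N, 6) step parameters (one row per circular step);
    ``step_types`` names the dinucleotide of each step; ``library`` maps
    step types to :class:`StepStiffness`.  Deviations are taken from the
    library mean of each step's type.

    Returns a record with totals in kB T and kcal/mol, per-step energies,
    and an exact component decomposition: per-parameter diagonal terms
    (``twist`` reported prominently as the twist energy) plus the summed
    off-diagonal coupling term.
    """
    structure = np.asarray(structure, dtype=float)
    if structure.ndim != 2 or structure.shape[1] != 6:
        raise ValueError(f"structure must be (n_steps, 6), got {structure.shape}")
    if len(step_types) != structure.shape[0]:
        raise ValueError(
            f"{len(step_types)} step types for {structure.shape[0]} structure rows"
        )
    missing = sorted({t for t in step_types if t not in library})
    if missing:
        raise ValueError(f"step types missing from stiffness library: {missing}")

    per_step = np.zeros(structure.shape[0])
    components = {name: 0.0 for name in PARAM_NAMES}
    coupling = 0.0
    temperature = None
    for i, (row, t) in enumerate(zip(structure, step_types)):
        entry = library[t]
        temperature = entry.temperature_K if temperature is None else temperature
        dp = row - entry.mean
        a = entry.stiffness_kt
        e = step_energy(dp, a)
        per_step[i] = e
        for k, name in enumerate(PARAM_NAMES):
            components[name] += 0.5 * a[k, k] * dp[k] ** 2
        coupling += e - sum(
            0.5 * a[k, k] * dp[k] ** 2 for k in range(6)
        )
    total_kt = float(per_step.sum())
    kt_to_kcal = KB_KCAL * (temperature if temperature is not None else 300.0)
    return {
        "total_kt": total_kt,
        "total_kcal_per_mol": total_kt * kt_to_kcal,
        "per_step_kt": per_step,
        "twist_energy_kt": components["twist"],
        "diagonal_components_kt": components,
        "coupling_kt": float(coupling),
    }


def mean_structure(frames: np.ndarray) -> np.ndarray:
    """Time-averaged structure from (n_frames, n_steps, 6) samples."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 6:
        raise ValueError(f"frames must be (n_frames, n_steps, 6), got {frames.shape}")
    return frames.mean(axis=0)
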