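"""Linking-number bookkeeping for closed circular DNA.

A closed duplex of ``n_bp`` base pairs with helical pitch ``p`` (bp per
turn) has relaxed linking number ``Lk0 = n_bp / p``.  The enforced integer
linking number ``Lk`` then defines the linking difference
``dLk = Lk - Lk0`` and the superhelical density ``sigma = dLk / Lk0``,
the dimensionless measure of topological stress.  Because coarse-grained
and atomistic forcefields assign slightly different intrinsic twists,
circles built for different engines at the *same* sigma need slightly
different sizes; :func:`size_correction` computes the compensating number
of base pairs for a given per-step twist deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_PITCH_BP_PER_TURN = 10.36
DEFAULT_TWIST_DEFICIT_DEG = 0.7


def superhelical_density(lk: float, lk0: float) -> float:
    """Return sigma = (Lk - Lk0) / Lk0.

    Parameters
    ----------
    lk : int
        Enforced linking number of the closed circle.
    lk0 : float
        Relaxed linking number; must be positive.
    """
    if lk0 <= 0:
        raise ValueError(f"lk0 must be positive, got {lk0}")
    return (lk - lk0) / lk0


def size_correction(
    n_bp: int,
    twist_deficit_deg: float = DEFAULT_TWIST_DEFICIT_DEG,
    pitch_bp_per_turn: float = DEFAULT_PITCH_BP_PER_TURN,
) -> int:
    """Extra base pairs needed to conserve total twist under a per-step deficit.

    If a forcefield underestimates the twist of every step by
    ``twist_deficit_deg``, a circle of ``n_bp`` base pairs is missing
    ``n_bp * deficit`` degrees of helical twist in total.  Adding
    ``round(n_bp * deficit / (360 / pitch))`` base pairs (round half to
    even) restores the total number of helical turns, keeping sigma
    comparable between engines.
    """
    if n_bp < 3:
        raise ValueError(f"n_bp must be >= 3, got {n_bp}")
    if pitch_bp_per_turn <= 0:
        raise ValueError(f"pitch must be positive, got {pitch_bp_per_turn}")
    per_bp_twist = 360.0 / pitch_bp_per_turn
    if not 0 <= twist_deficit_deg < per_bp_twist:
        raise ValueError(
            f"twist_deficit_deg must lie in [0, {per_bp_twist:.3f}), "
            f"got {twist_deficit_deg}"
        )
    return round(n_bp * twist_deficit_deg / per_bp_twist)


def lk0_from_step_twists(per_step_twists_deg) -> float:
    """Relaxed linking number of a circle built from the given step twists.

    Each base-pair step contributes ``twist / 360`` helical turns; the sum
    over all steps is Lk0.  Twists must lie in (0, 360) degrees.
    """
    twists = list(per_step_twists_deg)
    if not twists:
        raise ValueError("at least one step twist is required")
    for i, t in enumerate(twists):
        if not 0.0 < t < 360.0:
            raise ValueError(f"step twist {i} out of range (0, 360): {t}")
    return sum(twists) / 360.0


@dataclass(frozen=True)
class CircleTopology:
    """Topological state of a closed circular duplex.

    Attributes
    ----------
    n_bp : int
        Number of base pairs (>= 3).
    lk : int
        Enforced linking number.
    pitch_bp_per_turn : float
        Helical pitch used to assign the relaxed linking number.
    """

    n_bp: int
    lk: int
    pitch_bp_per_turn: float = DEFAULT_PITCH_BP_PER_TURN

    def __post_init__(self) -> None:
        if self.n_bp < 3:
            raise ValueError(f"n_bp must be >= 3, got {self.n_bp}")
        if self.pitch_bp_per_turn <= 0:
            raise ValueError(
                f"pitch must be positive, got {self.pitch_bp_per_turn}"
            )

    @property
    def lk0(self) -> float:
        return self.n_bp / self.pitch_bp_per_turn

    @property
    def delta_lk(self) -> float:
        return self.lk - self.lk0

    @property
    def sigma(self) -> float:
        return superhelical_density(self.lk, self.lk0)

    def corrected_n_bp(
        self, twist_deficit_deg: float = DEFAULT_TWIST_DEFICIT_DEG
    ) -> int:
        """Circle size after compensating a per-step twist deficit."""
        return self.n_bp + size_correction(
            self.n_bp, twist_deficit_deg, self.pitch_bp_per_turn
        )
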