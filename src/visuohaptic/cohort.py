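"""Synthetic behavioral cohorts with known latent structure.

The experiments' analyses take per-trial behavior (binary familiarity choices
and clipped pulling forces) as input. This module generates such trial logs
from an explicit generative model in which a single latent *learning strength*
``theta`` in [0, 1] drives performance on both tasks — the working hypothesis
of the analysis pipeline — so every downstream stage can be exercised against
known ground truth:

* pulling: force = (1-theta_eff) * separation_force + theta_eff * B_int +
  Gaussian noise, clipped to [0, 40] N, where B_int is the breakage force the
  participant's *internal* inventory implies (a participant may have
  internalized a wrong inventory in which two shapes are swapped between two
  true pairs — consistently wrong behavior, not noise);
* familiarity: the internally-true pair is chosen with probability
  0.5 + (p_max - 0.5) * (1 - exp(-theta_eff / lambda_gen));
* cross-modal phases attenuate expression by a multiplicative transfer gain:
  theta_eff = theta * transfer_gain for the haptic test after visual exposure
  and for the familiarity test after haptic-only exposure, theta otherwise;
* explicitness at debriefing is Binomial(n_true_pairs, theta * explicit_rate)
  / n_true_pairs, the 0..1 grid the debriefing produces.

``simulate_from_refb`` draws (rho, Tc, T) triples directly from the rectified
exponential-binomial observation model, for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .inventory import Inventory, build_inventory, swap_true_pairs
from .physics import BondConfig, annotate_breakage, split_contacts
from .scenes import (
    HAPTIC_EXPOSURE,
    STANDARD,
    VISUAL_EXPOSURE,
    FamiliarityTrial,
    GridScene,
    PullTrial,
    enumerate_exposure_scenes,
    generate_familiarity_design,
    generate_haptic_exposure_design,
    generate_pulling_test_design,
    generate_training_design,
    generate_visual_exposure_sequence,
)

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "experiment",
    "phase",
    "block",
    "trial_index",
    "scene_code",
    "pull_direction",
    "trial_mode",
    "breakage_force_N",
    "pull_force_N",
    "first_pair",
    "second_pair",
    "choice",
    "correct",
]

PHASE_VISUAL_EXPOSURE = "visual_exposure"
PHASE_TRAINING = "haptic_training"
PHASE_HAPTIC_EXPOSURE = "haptic_exposure"
PHASE_PULL_TEST = "haptic_pulling_test"
PHASE_FAMILIARITY = "familiarity_test"


@dataclass(frozen=True)
class ParticipantLatent:
    participant_id: int
    theta: float
    internal_inventory: Inventory
    sigma_pull: float
    transfer_gain: float
    explicit_rate: float

    def __post_init__(self):
        for name in ("theta", "transfer_gain", "explicit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.sigma_pull < 0:
            raise ConfigError("sigma_pull must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the published study design: 20 participants per
    experiment, a broad spread of learning strengths, pulling noise of a few
    newtons, near-ceiling asymptotic familiarity accuracy, and partial
    cross-modal transfer.
    """

    experiment: str = VISUAL_EXPOSURE
    n_participants: int = 20
    theta_a: float = 2.0  # Beta(a, b) prior over learning strength
    theta_b: float = 2.0
    sigma_pull: float = 4.0  # N
    p_max: float = 0.98  # asymptotic familiarity accuracy
    lambda_gen: float = 0.35  # rate of the generative familiarity link
    swap_probability: float = 0.1  # chance of an internally swapped inventory
    transfer_gain: float = 0.6  # cross-modal attenuation
    explicit_rate: float = 0.5
    seed: int = 0
    bond: BondConfig = field(default_factory=BondConfig)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.theta_a <= 0 or self.theta_b <= 0:
            raise ConfigError("Beta parameters must be positive")
        for name in ("p_max", "swap_probability", "transfer_gain", "explicit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.lambda_gen <= 0:
            raise ConfigError("lambda_gen must be positive")
        if self.experiment not in (VISUAL_EXPOSURE, HAPTIC_EXPOSURE):
            raise ConfigError(f"unknown experiment {self.experiment!r}")

    @property
    def inventory_shape(self) -> tuple[int, int]:
        return (3, 3) if self.experiment == VISUAL_EXPOSURE else (2, 2)


def sample_cohort(
    config: CohortConfig, inventory: Inventory | None = None
) -> tuple[Inventory, list[ParticipantLatent]]:
    """Draw a cohort of latent participants (seeded, reproducible).

    With probability ``swap_probability`` a participant's internal inventory
    has two shapes exchanged between two same-orientation true pairs.
    """
    rng = np.random.default_rng(config.seed)
    if inventory is None:
        n_h, n_v = config.inventory_shape
        inventory = build_inventory(n_h, n_v, seed=int(rng.integers(2**31)))
    participants = []
    thetas = rng.beta(config.theta_a, config.theta_b, size=config.n_participants)
    for i in range(config.n_participants):
        internal = inventory
        if rng.random() < config.swap_probability:
            internal = swap_true_pairs(inventory, rng)
        participants.append(
            ParticipantLatent(
                participant_id=i,
                theta=float(thetas[i]),
                internal_inventory=internal,
                sigma_pull=config.sigma_pull,
                transfer_gain=config.transfer_gain,
                explicit_rate=config.explicit_rate,
            )
        )
    return inventory, participants


def internal_breakage_force(
    scene: GridScene, direction: str, internal: Inventory, config: BondConfig
) -> float:
    """Breakage force the participant's internal inventory implies.

    A crossed contact is treated as intra-object when the two shapes on its
    sides form an internal true pair in the matching arrangement (left/right
    shapes across a horizontal contact, top/bottom across a vertical one).
    """
    cell_map = scene.cell_map
    total = 0.0
    for a, b in split_contacts(scene, direction):
        sa, sb = cell_map[a][0], cell_map[b][0]
        horizontal_contact = a[0] == b[0]
        bonded = any(
            (p.first == sa and p.second == sb)
            and ((p.orientation == "horizontal") == horizontal_contact)
            for p in internal.true_pairs
        )
        total += config.intra_object if bonded else config.inter_object
    return total


def _theta_eff(p: ParticipantLatent, cross_modal: bool) -> float:
    return p.theta * p.transfer_gain if cross_modal else p.theta


def simulate_pull_trial(
    p: ParticipantLatent,
    trial: PullTrial,
    config: BondConfig,
    rng: np.random.Generator,
    cross_modal: bool = False,
) -> float:
    """Simulated pulling force at the final beep, clipped to [0, force_cap].

    A naive participant (theta=0) pulls the 7.5 N separation force every
    competent pull requires; learning mixes in the internally predicted
    breakage force.
    """
    separation = 2 * config.inter_object
    if trial.configuration is not None:
        # training scenes have visible boundaries: the target force is known
        target = trial.breakage_force
    else:
        th = _theta_eff(p, cross_modal)
        b_int = internal_breakage_force(
            trial.scene, trial.direction, p.internal_inventory, config
        )
        target = (1.0 - th) * separation + th * b_int
    force = target + rng.normal(0.0, p.sigma_pull)
    return float(np.clip(force, 0.0, config.force_cap))


def familiarity_choice_probability(
    p: ParticipantLatent, p_max: float, lambda_gen: float, cross_modal: bool = False
) -> float:
    """Probability of choosing the internally-true pair (saturating link)."""
    th = _theta_eff(p, cross_modal)
    return 0.5 + (p_max - 0.5) * (1.0 - np.exp(-th / lambda_gen))


def simulate_familiarity_trial(
    p: ParticipantLatent,
    trial: FamiliarityTrial,
    p_max: float,
    lambda_gen: float,
    rng: np.random.Generator,
    cross_modal: bool = False,
) -> str:
    """Simulated choice ("first" or "second").

    The pair that is a true pair *under the participant's internal inventory*
    is chosen with the link probability; when neither or both presented pairs
    are internally true the choice is a fair coin. Internal truth is
    arrangement-specific (orientation and shape roles must match, as in the
    displayed pair): a learned object is a spatial configuration of shapes,
    not a bag of shapes.
    """

    def internally_true(pair):
        return any(
            q.orientation == pair.orientation
            and q.first == pair.first
            and q.second == pair.second
            for q in p.internal_inventory.true_pairs
        )

    first_true = internally_true(trial.first)
    second_true = internally_true(trial.second)
    if first_true == second_true:
        return "first" if rng.random() < 0.5 else "second"
    prob = familiarity_choice_probability(p, p_max, lambda_gen, cross_modal)
    internal_pick = "first" if first_true else "second"
    other = "second" if first_true else "first"
    return internal_pick if rng.random() < prob else other


def _pull_rows(p, trials, phase, experiment, rng, bond, cross_modal, simulate=True):
    rows = []
    for i, t in enumerate(trials):
        if t.mode == STANDARD or not simulate:
            # standard trials end at breakage; the exerted force equals it
            force = min(t.breakage_force, bond.force_cap) if simulate else np.nan
        else:
            force = simulate_pull_trial(p, t, bond, rng, cross_modal)
        rows.append(
            {
                "participant_id": p.participant_id,
                "experiment": experiment,
                "phase": phase,
                "block": t.block_index,
                "trial_index": i,
                "scene_code": t.scene.scene_code() if t.scene is not None else t.configuration,
                "pull_direction": t.direction,
                "trial_mode": t.mode,
                "breakage_force_N": t.breakage_force,
                "pull_force_N": force,
                "first_pair": "",
                "second_pair": "",
                "choice": "",
                "correct": "",
            }
        )
    return rows


def _familiarity_rows(p, trials, experiment, config, rng, cross_modal):
    rows = []
    for i, t in enumerate(trials):
        choice = simulate_familiarity_trial(
            p, t, config.p_max, config.lambda_gen, rng, cross_modal
        )
        rows.append(
            {
                "participant_id": p.participant_id,
                "experiment": experiment,
                "phase": PHASE_FAMILIARITY,
                "block": t.block_index,
                "trial_index": i,
                "scene_code": "",
                "pull_direction": "",
                "trial_mode": "",
                "breakage_force_N": np.nan,
                "pull_force_N": np.nan,
                "first_pair": t.first.pair_id,
                "second_pair": t.second.pair_id,
                "choice": choice,
                "correct": int(choice == t.correct_position),
            }
        )
    return rows


def simulate_experiment(
    config: CohortConfig,
    inventory: Inventory | None = None,
    include_exposure: bool = True,
) -> tuple[pd.DataFrame, Inventory, list[ParticipantLatent]]:
    """Simulate a full cohort through every phase of one experiment.

    Returns the trial log (one row per trial per participant, schema
    ``TRIAL_LOG_COLUMNS``), the generative inventory, and the latent cohort.
    ``include_exposure=False`` drops the (response-free) visual-exposure rows
    and the haptic-exposure/training rows, keeping only the two test phases —
    useful for analyses that never touch exposure behavior.
    """
    inventory, cohort = sample_cohort(config, inventory)
    master = np.random.default_rng(config.seed + 1)
    bond = config.bond
    rows: list[dict] = []
    exp = config.experiment

    if exp == VISUAL_EXPOSURE:
        scenes, _ = enumerate_exposure_scenes(inventory) if include_exposure else ([], None)
        for p in cohort:
            rng = np.random.default_rng(master.integers(2**31))
            dseed = int(master.integers(2**31))
            if include_exposure:
                seq = generate_visual_exposure_sequence(scenes, seed=dseed)
                for i, s in enumerate(seq):
                    rows.append(
                        {
                            "participant_id": p.participant_id,
                            "experiment": exp,
                            "phase": PHASE_VISUAL_EXPOSURE,
                            "block": 0,
                            "trial_index": i,
                            "scene_code": s.scene_code(),
                            "pull_direction": "",
                            "trial_mode": "",
                            "breakage_force_N": np.nan,
                            "pull_force_N": np.nan,
                            "first_pair": "",
                            "second_pair": "",
                            "choice": "",
                            "correct": "",
                        }
                    )
                training = annotate_breakage(
                    generate_training_design(exp, seed=dseed + 1), bond
                )
                rows += _pull_rows(p, training, PHASE_TRAINING, exp, rng, bond, False)
            pull = annotate_breakage(
                generate_pulling_test_design(exp, inventory, seed=dseed + 2), bond
            )
            # haptic test after visual exposure is cross-modal
            rows += _pull_rows(p, pull, PHASE_PULL_TEST, exp, rng, bond, True)
            fam = generate_familiarity_design(inventory, n_blocks=2, seed=dseed + 3)
            rows += _familiarity_rows(p, fam, exp, config, rng, False)
    else:
        for p in cohort:
            rng = np.random.default_rng(master.integers(2**31))
            dseed = int(master.integers(2**31))
            if include_exposure:
                training = annotate_breakage(
                    generate_training_design(exp, seed=dseed + 1), bond
                )
                rows += _pull_rows(p, training, PHASE_TRAINING, exp, rng, bond, False)
                exposure = annotate_breakage(
                    generate_haptic_exposure_design(inventory, n_blocks=4, seed=dseed), bond
                )
                rows += _pull_rows(p, exposure, PHASE_HAPTIC_EXPOSURE, exp, rng, bond, False)
            pull = annotate_breakage(
                generate_pulling_test_design(exp, inventory, seed=dseed + 2), bond
            )
            rows += _pull_rows(p, pull, PHASE_PULL_TEST, exp, rng, bond, False)
            fam = generate_familiarity_design(inventory, n_blocks=2, seed=dseed + 3)
            # familiarity after haptic-only exposure is cross-modal
            rows += _familiarity_rows(p, fam, exp, config, rng, True)

    log = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
    return log, inventory, cohort


def simulate_debriefing(
    config: CohortConfig, cohort: list[ParticipantLatent], inventory: Inventory
) -> pd.DataFrame:
    """Debriefing records: number of correctly identified true pairs per
    participant, Binomial(n_true_pairs, theta * explicit_rate)."""
    rng = np.random.default_rng(config.seed + 2)
    n_true = len(inventory.true_pairs)
    recs = []
    for p in cohort:
        n_correct = int(rng.binomial(n_true, p.theta * p.explicit_rate))
        recs.append(
            {
                "participant_id": p.participant_id,
                "noticed": n_correct > 0,
                "n_correct_pairs": n_correct,
                "n_true_pairs": n_true,
            }
        )
    return pd.DataFrame(recs)


def simulate_from_refb(
    params,
    n_participants: int,
    T: int,
    rho_range: tuple[float, float] = (-0.1, 0.9),
    seed: int = 0,
) -> list[tuple[float, int, int]]:
    """Draw (rho_i, Tc_i, T) triples from the rectified exponential-binomial.

    rho_i is uniform on ``rho_range`` and Tc_i binomial with success
    probability P(rho_i). Used for parameter-recovery and calibration studies.
    """
    from .reb import refb_probability

    lo, hi = rho_range
    if not (-1.0 <= lo <= hi <= 1.0):
        raise ConfigError("rho_range must be within [-1, 1]")
    rng = np.random.default_rng(seed)
    rho = rng.uniform(lo, hi, size=n_participants)
    prob = refb_probability(params, rho)
    tc = rng.binomial(T, prob)
    return [(float(r), int(c), int(T)) for r, c in zip(rho, tc)]
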