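"""Bond model for scene breakage forces.

Every occupied cell of a pull scene belongs to one haptic *object*: a true
pair is a single object spanning its two cells, a pseudo pair's shapes are two
separate single-cell objects, and the training rectangles/squares map per
visible piece. Adjacent cells are attached by 11.25 N when they belong to the
same object and 3.75 N when they belong to different objects. The breakage
force of a pull is the sum of the bond strengths crossed by the mid-line split
implied by the pulling direction, which yields the three levels of the task:

======================  ==========  ==============
scene                   hard pull   orthogonal pull
======================  ==========  ==============
true + true             22.5 N      7.5 N
true + pseudo           15.0 N      7.5 N
pseudo + pseudo         7.5 N       7.5 N
======================  ==========  ==============

(hard = pulling parallel to the boundary between the pairs, so that each
pair's internal contact is crossed). Training configurations C2 (two
rectangles), C3 (rectangle + two squares) and C4 (four squares) follow the
same rule: 22.5/7.5, 15/7.5 and 7.5/7.5 N.

Forces are static thresholds; no time-resolved spring simulation. The 40 N
measurement cap and the 5 N pull-onset threshold are carried here as
configuration but applied by the behavior simulator and measures.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigError, UnsupportedSceneError
from .inventory import HORIZONTAL, TRUE, VERTICAL
from .scenes import C2, C3, C4, GridScene, PullTrial


@dataclass(frozen=True)
class BondConfig:
    intra_object: float = 11.25  # N, contact within one object
    inter_object: float = 3.75  # N, contact between different objects
    force_cap: float = 40.0  # N, measurement clipping of pulling forces
    pull_threshold: float = 5.0  # N, pull-onset threshold (beeps start)

    def __post_init__(self):
        if min(self.intra_object, self.inter_object, self.force_cap, self.pull_threshold) <= 0:
            raise ConfigError("all bond-config values must be positive")
        if self.intra_object <= self.inter_object:
            raise ConfigError("intra-object bond must exceed inter-object bond")


ObjectMap = dict[tuple[int, int], int]  # cell -> object id


def object_map(scene: GridScene) -> ObjectMap:
    """Haptic object assignment for a pair scene: true pairs are one object
    across both cells, pseudo-pair shapes are separate objects."""
    out: ObjectMap = {}
    next_id = 0
    for pl in scene.placements:
        cells = pl.cells
        if pl.pair.kind == TRUE:
            for cell in cells:
                out[cell] = next_id
            next_id += 1
        else:
            for cell in cells:
                out[cell] = next_id
                next_id += 1
    return out


def split_contacts(
    scene: GridScene, direction: str
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Edge contacts crossed by the mid-line split of a 2x2 scene.

    Horizontal pulling parts the scene into left/right halves (vertical
    mid-line, one contact per row); vertical pulling into top/bottom halves
    (one contact per column).
    """
    if scene.n_rows != 2 or scene.n_cols != 2 or len(scene.occupied) != 4:
        raise UnsupportedSceneError("split_contacts is defined for full 2x2 scenes")
    if direction == HORIZONTAL:
        return [((r, 0), (r, 1)) for r in range(2)]
    if direction == VERTICAL:
        return [((0, c), (1, c)) for c in range(2)]
    raise UnsupportedSceneError(f"unknown pulling direction {direction!r}")


def breakage_force(
    scene: GridScene,
    direction: str,
    objects: ObjectMap | None = None,
    config: BondConfig = BondConfig(),
) -> float:
    """Bond-sum breakage force of a 2x2 pair scene for the given pull."""
    if objects is None:
        objects = object_map(scene)
    total = 0.0
    for a, b in split_contacts(scene, direction):
        total += config.intra_object if objects[a] == objects[b] else config.inter_object
    return total


def training_breakage_force(
    configuration: str,
    orientation: str,
    direction: str,
    config: BondConfig = BondConfig(),
) -> float:
    """Breakage force of a training scene (coloured rectangles/squares).

    ``orientation`` is the long axis of the rectangle(s); the hard pull is the
    one parallel to it (crossing the rectangles' internal contacts).
    """
    if configuration not in (C2, C3, C4):
        raise UnsupportedSceneError(f"unknown training configuration {configuration!r}")
    if orientation not in (HORIZONTAL, VERTICAL) or direction not in (HORIZONTAL, VERTICAL):
        raise UnsupportedSceneError("invalid orientation/direction")
    hard = orientation == direction
    if configuration == C4 or not hard:
        return 2 * config.inter_object
    if configuration == C2:
        return 2 * config.intra_object
    return config.intra_object + config.inter_object  # C3, hard direction


def annotate_breakage(
    trials: list[PullTrial], config: BondConfig = BondConfig()
) -> list[PullTrial]:
    """Attach breakage forces to a list of pull trials (inventory or training)."""
    out = []
    for t in trials:
        if t.configuration is not None:
            f = training_breakage_force(t.configuration, t.train_orientation, t.direction, config)
        else:
            f = breakage_force(t.scene, t.direction, config=config)
        out.append(t.with_force(f))
    return out
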