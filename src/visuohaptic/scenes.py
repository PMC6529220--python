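"""Grid scenes and experimental-design generation.

The exposure and test stimuli of both experiments are *grid scenes*: placements
of shape pairs on a small rectangular grid, with each pair occupying two
edge-adjacent cells matching its orientation. This module

* represents and canonicalizes grid scenes (translation-equivalent placements
  are the same scene),
* exhaustively enumerates the visual-exposure scene set — all placements of 3
  distinct true pairs on a 3x3 grid such that every pair touches another pair,
  the centre cell is occupied, and translates are deduplicated (444 scenes for
  the standard 3H+3V inventory),
* generates the per-phase trial designs: haptic exposure blocks, pulling-test
  blocks, two-alternative familiarity blocks, and the coloured-rectangle
  training schedules.

Design generators are exhaustive-by-block: within a block the prescribed
combinatorial structure (every combination, order, and pulling direction) is
covered exactly once, then shuffled by seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .exceptions import InvalidInventoryError, InvalidSceneError
from .inventory import HORIZONTAL, PSEUDO, TRUE, VERTICAL, Inventory, PairSpec

# pulling directions: horizontal pulling parts the scene into left/right
# halves (vertical mid-line); vertical pulling into top/bottom halves.
DIRECTIONS = (HORIZONTAL, VERTICAL)

STANDARD = "standard"
CLAMP = "clamp"
CLAMP_CATCH = "clamp_catch"

# Stimulus timing (metadata constants; no simulated clocks)
DISPLAY_MS = 700
PAUSE_MS = 1000
HOLD_BEFORE_PULL_S = 3


@dataclass(frozen=True)
class Placement:
    pair: PairSpec
    row: int  # anchor: top-left cell of the pair
    col: int

    @property
    def cells(self) -> tuple[tuple[int, int], tuple[int, int]]:
        if self.pair.orientation == HORIZONTAL:
            return ((self.row, self.col), (self.row, self.col + 1))
        return ((self.row, self.col), (self.row + 1, self.col))


@dataclass(frozen=True)
class GridScene:
    n_rows: int
    n_cols: int
    placements: tuple[Placement, ...]

    def __post_init__(self):
        seen: set[tuple[int, int]] = set()
        for pl in self.placements:
            for r, c in pl.cells:
                if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                    raise InvalidSceneError(
                        f"pair {pl.pair.pair_id} cell {(r, c)} outside "
                        f"{self.n_rows}x{self.n_cols} grid"
                    )
                if (r, c) in seen:
                    raise InvalidSceneError(f"overlapping placements at {(r, c)}")
                seen.add((r, c))

    @property
    def cell_map(self) -> dict[tuple[int, int], tuple[int, int]]:
        """cell -> (shape_id, pair_id)."""
        out = {}
        for pl in self.placements:
            (r1, c1), (r2, c2) = pl.cells
            out[(r1, c1)] = (pl.pair.first, pl.pair.pair_id)
            out[(r2, c2)] = (pl.pair.second, pl.pair.pair_id)
        return out

    @property
    def occupied(self) -> set[tuple[int, int]]:
        return {c for pl in self.placements for c in pl.cells}

    def key(self) -> frozenset[tuple[int, int, int]]:
        """Identity key: set of (pair_id, anchor_row, anchor_col)."""
        return frozenset((pl.pair.pair_id, pl.row, pl.col) for pl in self.placements)

    def scene_code(self) -> str:
        """Compact string code, e.g. ``"0@0,0;4@1,2"`` (0-based anchors)."""
        parts = sorted(
            (pl.pair.pair_id, pl.row, pl.col) for pl in self.placements
        )
        return ";".join(f"{pid}@{r},{c}" for pid, r, c in parts)


def scene_from_code(code: str, inventory: Inventory, n_rows: int, n_cols: int) -> GridScene:
    """Inverse of :meth:`GridScene.scene_code` given the inventory."""
    placements = []
    for part in code.split(";"):
        pid, anchor = part.split("@")
        r, c = anchor.split(",")
        placements.append(Placement(inventory.pair_by_id(int(pid)), int(r), int(c)))
    return GridScene(n_rows, n_cols, tuple(placements))


def canonicalize(scene: GridScene) -> GridScene:
    """Translate a scene so its bounding box touches row 0 and column 0.

    Identity-preserving (pair ids and relative geometry unchanged) and
    idempotent; scenes that differ only by translation share a canonical form.
    """
    occ = scene.occupied
    dr = min(r for r, _ in occ)
    dc = min(c for _, c in occ)
    if dr == 0 and dc == 0:
        return scene
    moved = tuple(Placement(pl.pair, pl.row - dr, pl.col - dc) for pl in scene.placements)
    return GridScene(scene.n_rows, scene.n_cols, moved)


def _pairs_touch(a: Placement, b: Placement) -> bool:
    return any(
        abs(r1 - r2) + abs(c1 - c2) == 1 for r1, c1 in a.cells for r2, c2 in b.cells
    )


def is_valid_exposure_scene(scene: GridScene) -> bool:
    """Standalone re-check of the three exposure-scene constraints.

    (1) every pair has at least one cell edge-adjacent (4-neighbourhood) to a
    cell of another pair; (2) the centre cell of the 3x3 grid is occupied by
    *some* translate of the scene within the grid — for scenes already on the
    3x3 grid this is simply centre-cell occupancy; (3) is a statement about
    the scene *set* (translation dedup), not a single scene.
    """
    if scene.n_rows != 3 or scene.n_cols != 3:
        return False
    pls = scene.placements
    for i, a in enumerate(pls):
        if not any(_pairs_touch(a, b) for j, b in enumerate(pls) if j != i):
            return False
    return (1, 1) in scene.occupied


# scene categories: orientation multiset plus relative offset of the two
# same-orientation pairs (aligned = same columns for H, same rows for V)
CATEGORIES = ("3H", "3V", "2H1V_aligned", "2H1V_offset", "2V1H_aligned", "2V1H_offset")


def categorize(scene: GridScene) -> str:
    orients = sorted(pl.pair.orientation for pl in scene.placements)
    if orients == [HORIZONTAL] * 3:
        return "3H"
    if orients == [VERTICAL] * 3:
        return "3V"
    n_h = orients.count(HORIZONTAL)
    if n_h == 2:
        hs = [pl for pl in scene.placements if pl.pair.orientation == HORIZONTAL]
        return "2H1V_aligned" if hs[0].col == hs[1].col else "2H1V_offset"
    vs = [pl for pl in scene.placements if pl.pair.orientation == VERTICAL]
    return "2V1H_aligned" if vs[0].row == vs[1].row else "2V1H_offset"


def _anchor_slots(orientation: str, n_rows: int = 3, n_cols: int = 3):
    if orientation == HORIZONTAL:
        return [(r, c) for r in range(n_rows) for c in range(n_cols - 1)]
    return [(r, c) for r in range(n_rows - 1) for c in range(n_cols)]


def enumerate_exposure_scenes(
    inventory: Inventory,
) -> tuple[list[GridScene], dict[str, int]]:
    """Exhaustively enumerate the visual-exposure scene set.

    All canonical placements of 3 *distinct* true pairs on the 3x3 grid such
    that every pair is edge-adjacent to another pair, the centre cell is
    occupied, and translation-equivalent placements are counted once. Scenes
    with the same geometry but different pair identities are distinct.

    Returns the scene list and per-category counts. For the standard inventory
    (3 horizontal + 3 vertical true pairs) this yields 444 scenes: 42 per
    three-same-orientation category, 108 per two-aligned category, 72 per
    two-offset category, with every pair appearing in 222 scenes.
    """
    if inventory.n_true_h != 3 or inventory.n_true_v != 3:
        raise InvalidInventoryError(
            "exposure enumeration requires 3 horizontal + 3 vertical true pairs"
        )
    pairs = inventory.true_pairs
    seen: set[frozenset] = set()
    scenes: list[GridScene] = []
    counts = {c: 0 for c in CATEGORIES}
    for trio in combinations(pairs, 3):
        slot_sets = [_anchor_slots(p.orientation) for p in trio]
        for anchors in product(*slot_sets):
            try:
                scene = GridScene(
                    3, 3, tuple(Placement(p, r, c) for p, (r, c) in zip(trio, anchors))
                )
            except InvalidSceneError:
                continue
            if not is_valid_exposure_scene(scene):
                continue
            canon = canonicalize(scene)
            k = canon.key()
            if k in seen:
                continue
            seen.add(k)
            scenes.append(canon)
            counts[categorize(canon)] += 1
    return scenes, counts


def make_2x2_scene(
    pair_a: PairSpec, pair_b: PairSpec, orientation: str, order: str = "ab"
) -> GridScene:
    """Stack two same-orientation pairs into a 2x2 block.

    Horizontal pairs are stacked vertically (``order='ab'`` puts ``pair_a`` in
    row 0); vertical pairs sit side by side (``order='ab'`` puts ``pair_a`` in
    column 0).
    """
    if pair_a.orientation != orientation or pair_b.orientation != orientation:
        raise InvalidSceneError("both pairs must match the stated orientation")
    if pair_a.pair_id == pair_b.pair_id:
        raise InvalidSceneError("a 2x2 scene needs two distinct pairs")
    if order not in ("ab", "ba"):
        raise InvalidSceneError(f"order must be 'ab' or 'ba', got {order!r}")
    first, second = (pair_a, pair_b) if order == "ab" else (pair_b, pair_a)
    if orientation == HORIZONTAL:
        pls = (Placement(first, 0, 0), Placement(second, 1, 0))
    else:
        pls = (Placement(first, 0, 0), Placement(second, 0, 1))
    return GridScene(2, 2, pls)


def generate_visual_exposure_sequence(
    scenes: list[GridScene], seed: int
) -> list[GridScene]:
    """Seeded uniform permutation of the exposure scene set."""
    if not scenes:
        raise InvalidSceneError("empty scene set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    return [scenes[i] for i in order]


# ---------------------------------------------------------------------------
# Pull / familiarity trial records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PullTrial:
    """One pulling trial.

    ``scene`` is a 2x2 pair scene for inventory phases; training trials carry
    ``configuration`` (C2/C3/C4) and ``train_orientation`` (the rectangle
    orientation) instead, with ``scene=None``. ``breakage_force`` is annotated
    by the haptic physics module.
    """

    scene: GridScene | None
    direction: str
    mode: str
    block_index: int
    breakage_force: float = float("nan")
    configuration: str | None = None  # training only: C2 | C3 | C4
    train_orientation: str | None = None  # training only

    def with_force(self, force: float) -> "PullTrial":
        return PullTrial(
            self.scene,
            self.direction,
            self.mode,
            self.block_index,
            float(force),
            self.configuration,
            self.train_orientation,
        )


@dataclass(frozen=True)
class FamiliarityTrial:
    """One two-alternative familiarity trial: a true pair versus a pseudo pair
    of the same orientation, in one of the two presentation orders."""

    first: PairSpec
    second: PairSpec
    correct_position: str  # "first" | "second"
    block_index: int

    def __post_init__(self):
        kinds = {self.first.kind, self.second.kind}
        if kinds != {TRUE, PSEUDO}:
            raise InvalidSceneError("familiarity trial needs one true + one pseudo pair")
        if self.first.orientation != self.second.orientation:
            raise InvalidSceneError("familiarity pairs must share orientation")
        true_pos = "first" if self.first.kind == TRUE else "second"
        if self.correct_position != true_pos:
            raise InvalidSceneError("correct_position must point at the true pair")


def _shuffle_blocks(trials, block_sizes, rng):
    """Shuffle each block independently, preserving block order."""
    out = []
    start = 0
    for size in block_sizes:
        block = trials[start : start + size]
        order = rng.permutation(size)
        out.extend(block[i] for i in order)
        start += size
    return out


def _require_2plus2(inventory: Inventory) -> None:
    ok = (
        inventory.n_true_h == 2
        and inventory.n_true_v == 2
        and len(inventory.pseudo_pairs) == 4
    )
    if not ok:
        raise InvalidInventoryError(
            "haptic-exposure designs require 2 true + 2 pseudo pairs per orientation"
        )


def _haptic_exposure_block(inventory: Inventory, block_index: int, mode: str):
    """One 48-trial block: every unordered same-orientation combination of two
    pairs (true or pseudo), in both arrangement orders and both pulling
    directions."""
    trials = []
    for orientation in (HORIZONTAL, VERTICAL):
        pool = inventory.pairs_of(TRUE, orientation) + inventory.pairs_of(
            PSEUDO, orientation
        )
        for a, b in combinations(pool, 2):
            for order in ("ab", "ba"):
                scene = make_2x2_scene(a, b, orientation, order)
                for direction in DIRECTIONS:
                    trials.append(PullTrial(scene, direction, mode, block_index))
    return trials


def generate_haptic_exposure_design(
    inventory: Inventory, n_blocks: int = 4, seed: int = 0
) -> list[PullTrial]:
    """Haptic statistical exposure: ``n_blocks`` 48-trial standard blocks.

    Per block: 8 true-true, 8 pseudo-pseudo and 32 true-pseudo scenes (each
    combination in both arrangement orders and both pulling directions),
    shuffled within block. The default 4 blocks give the 192 standard trials
    of the haptic-exposure experiment.
    """
    _require_2plus2(inventory)
    rng = np.random.default_rng(seed)
    trials = []
    for b in range(n_blocks):
        trials.extend(_haptic_exposure_block(inventory, b, STANDARD))
    return _shuffle_blocks(trials, [48] * n_blocks, rng)


VISUAL_EXPOSURE = "visual_exposure"
HAPTIC_EXPOSURE = "haptic_exposure"


def generate_pulling_test_design(
    experiment: str, inventory: Inventory, seed: int = 0
) -> list[PullTrial]:
    """Haptic pulling test design.

    visual_exposure experiment: 2 blocks of 24 clamp-catch trials; within a
    block, each ordered combination of two same-orientation *true* pairs
    appears once per pulling direction (12 unique scenes x 2 directions).

    haptic_exposure experiment: one 48-trial clamp block mirroring the
    composition of a haptic-exposure block (true and pseudo pairs).
    """
    rng = np.random.default_rng(seed)
    if experiment == VISUAL_EXPOSURE:
        if inventory.n_true_h != 3 or inventory.n_true_v != 3:
            raise InvalidInventoryError(
                "visual-exposure pulling test requires the 3+3 inventory"
            )
        trials = []
        for b in range(2):
            block = []
            for orientation in (HORIZONTAL, VERTICAL):
                tp = inventory.pairs_of(TRUE, orientation)
                for a, bpair in combinations(tp, 2):
                    for order in ("ab", "ba"):
                        scene = make_2x2_scene(a, bpair, orientation, order)
                        for direction in DIRECTIONS:
                            block.append(PullTrial(scene, direction, CLAMP_CATCH, b))
            # each ordered combination once per direction: 12 scenes x 2 = 24
            trials.extend(block)
        return _shuffle_blocks(trials, [24, 24], rng)
    if experiment == HAPTIC_EXPOSURE:
        _require_2plus2(inventory)
        trials = _haptic_exposure_block(inventory, 0, CLAMP)
        return _shuffle_blocks(trials, [48], rng)
    raise InvalidInventoryError(f"unknown experiment {experiment!r}")


def generate_familiarity_design(
    inventory: Inventory, n_blocks: int = 2, seed: int = 0
) -> list[FamiliarityTrial]:
    """Two-alternative familiarity test design.

    Within every block each true pair is compared to each pseudo pair of the
    same orientation in each presentation order exactly once, then the block
    is shuffled. Block size is ``2 * sum_orientation(n_true * n_pseudo)``:
    36 for the 3+3 inventory, 16 for the 2+2 inventory.
    """
    rng = np.random.default_rng(seed)
    trials = []
    block_size = None
    for b in range(n_blocks):
        block = []
        for orientation in (HORIZONTAL, VERTICAL):
            for t in inventory.pairs_of(TRUE, orientation):
                for p in inventory.pairs_of(PSEUDO, orientation):
                    block.append(FamiliarityTrial(t, p, "first", b))
                    block.append(FamiliarityTrial(p, t, "second", b))
        block_size = len(block)
        trials.extend(block)
    return _shuffle_blocks(trials, [block_size] * n_blocks, rng)


# ---------------------------------------------------------------------------
# Training designs (coloured rectangles, configurations C2/C3/C4)
# ---------------------------------------------------------------------------

C2, C3, C4 = "C2", "C3", "C4"


def _training_trials(configs, mode, block_index, rng):
    """Each scene drawn with a random orientation and pulled in both
    directions on consecutive trials (the orthogonal pull repeats the scene)."""
    trials = []
    order = rng.permutation(len(configs))
    for i in order:
        cfg = configs[i]
        orientation = HORIZONTAL if rng.random() < 0.5 else VERTICAL
        dirs = list(DIRECTIONS)
        rng.shuffle(dirs)
        for direction in dirs:
            trials.append(
                PullTrial(
                    None,
                    direction,
                    mode,
                    block_index,
                    configuration=cfg,
                    train_orientation=orientation,
                )
            )
    return trials


def generate_training_design(experiment: str, seed: int = 0) -> list[PullTrial]:
    """Haptic task training with coloured-rectangle scenes.

    visual_exposure: 56 trials — 24 standard, 16 clamp, 16 clamp-catch, all
    C2 scenes (two rectangles).

    haptic_exposure: 144 trials — two 48-trial standard blocks followed by one
    48-trial clamp block, each composed of 8 C2, 8 C4 and 32 C3 scenes in
    pseudorandom order and orientation (matching the exposure-phase force-level
    proportions).
    """
    rng = np.random.default_rng(seed)
    if experiment == VISUAL_EXPOSURE:
        trials = []
        for mode, n in ((STANDARD, 24), (CLAMP, 16), (CLAMP_CATCH, 16)):
            trials.extend(_training_trials([C2] * (n // 2), mode, 0, rng))
        return trials
    if experiment == HAPTIC_EXPOSURE:
        composition = [C2] * 4 + [C4] * 4 + [C3] * 16  # x2 directions = 48 trials
        trials = []
        for b, mode in enumerate((STANDARD, STANDARD, CLAMP)):
            trials.extend(_training_trials(composition, mode, b, rng))
        return trials
    raise InvalidInventoryError(f"unknown experiment {experiment!r}")
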