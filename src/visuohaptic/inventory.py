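"""Shape inventories: true pairs (objects) and chimeric pseudo pairs.

An inventory holds ``2 * (n_true_h + n_true_v)`` abstract shapes grouped into
horizontal and vertical *true pairs* — the objects of the experiment, whose
shapes always co-occur in a fixed spatial arrangement and are haptically bonded
— plus an equal number of *pseudo pairs*. Each horizontal pseudo pair re-uses
one "top" and one "bottom" shape from two different vertical true pairs (and
symmetrically for vertical pseudo pairs from horizontal donors), so pseudo
pairs have matched visual co-occurrence statistics but never reproduce a true
pair, and every shape belongs to exactly one true pair and one pseudo pair.

Shapes are plain integer ids; their visual appearance is irrelevant to every
analysis downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInventoryError, MissingSeedError

HORIZONTAL = "horizontal"
VERTICAL = "vertical"
TRUE = "true"
PSEUDO = "pseudo"


@dataclass(frozen=True)
class PairSpec:
    """A single pair of shapes.

    ``first`` is the left shape for a horizontal pair and the top shape for a
    vertical pair; ``second`` the right/bottom one.
    """

    pair_id: int
    kind: str  # "true" | "pseudo"
    orientation: str  # "horizontal" | "vertical"
    first: int
    second: int

    def __post_init__(self):
        if self.first == self.second:
            raise InvalidInventoryError(
                f"pair {self.pair_id}: first and second shape must differ"
            )
        if self.kind not in (TRUE, PSEUDO):
            raise InvalidInventoryError(f"unknown pair kind {self.kind!r}")
        if self.orientation not in (HORIZONTAL, VERTICAL):
            raise InvalidInventoryError(f"unknown orientation {self.orientation!r}")

    @property
    def shapes(self) -> frozenset[int]:
        return frozenset((self.first, self.second))


@dataclass
class Inventory:
    n_true_h: int
    n_true_v: int
    true_pairs: list[PairSpec]
    pseudo_pairs: list[PairSpec]
    seed: int
    n_shapes: int = field(init=False)

    def __post_init__(self):
        self.n_shapes = 2 * (self.n_true_h + self.n_true_v)

    @property
    def pairs(self) -> list[PairSpec]:
        return self.true_pairs + self.pseudo_pairs

    def pair_by_id(self, pair_id: int) -> PairSpec:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)

    def true_pair_shapesets(self) -> set[frozenset[int]]:
        return {p.shapes for p in self.true_pairs}

    def pairs_of(self, kind: str, orientation: str) -> list[PairSpec]:
        pool = self.true_pairs if kind == TRUE else self.pseudo_pairs
        return [p for p in pool if p.orientation == orientation]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def pair_dict(p: PairSpec) -> dict:
            return {
                "pair_id": p.pair_id,
                "kind": p.kind,
                "orientation": p.orientation,
                "first": p.first,
                "second": p.second,
            }

        return {
            "n_true_h": self.n_true_h,
            "n_true_v": self.n_true_v,
            "seed": self.seed,
            "true_pairs": [pair_dict(p) for p in self.true_pairs],
            "pseudo_pairs": [pair_dict(p) for p in self.pseudo_pairs],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Inventory":
        mk = lambda pd: PairSpec(**pd)
        return cls(
            n_true_h=d["n_true_h"],
            n_true_v=d["n_true_v"],
            true_pairs=[mk(p) for p in d["true_pairs"]],
            pseudo_pairs=[mk(p) for p in d["pseudo_pairs"]],
            seed=d["seed"],
        )

    @classmethod
    def from_json(cls, s: str) -> "Inventory":
        return cls.from_dict(json.loads(s))


def build_inventory(n_true_h: int, n_true_v: int, seed: int) -> Inventory:
    """Build a randomized inventory of true and pseudo pairs.

    Parameters
    ----------
    n_true_h, n_true_v
        Number of horizontal and vertical true pairs. Both must be at least 2:
        each pseudo pair draws its two shapes from two *different* donor true
        pairs of the opposite orientation, which is impossible with a single
        donor.
    seed
        Drives the shape-to-pair assignment and the donor matching. Required.

    Returns
    -------
    Inventory
        ``2*(n_true_h+n_true_v)`` shapes; pseudo pairs exactly partition the
        shape set, with orientations swapped relative to their donors.

    Notes
    -----
    Donor matching is cyclic after a seeded permutation of donor order: pseudo
    pair *i* takes the top/left shape of donor *i* and the bottom/right shape
    of donor *i+1 (mod n)*. Any matching in which the two shapes come from two
    different donors and keep their top/bottom (left/right) roles is
    admissible; the cyclic rule is deterministic and satisfies that for n >= 2.
    """
    if seed is None:
        raise MissingSeedError("build_inventory requires an explicit seed")
    if n_true_h < 2 or n_true_v < 2:
        raise InvalidInventoryError(
            "need at least 2 true pairs per orientation to build pseudo pairs "
            f"(got n_true_h={n_true_h}, n_true_v={n_true_v})"
        )
    rng = np.random.default_rng(seed)
    n_shapes = 2 * (n_true_h + n_true_v)
    shapes = rng.permutation(n_shapes)

    true_pairs: list[PairSpec] = []
    k = 0
    for i in range(n_true_h):
        true_pairs.append(
            PairSpec(i, TRUE, HORIZONTAL, int(shapes[k]), int(shapes[k + 1]))
        )
        k += 2
    for i in range(n_true_v):
        true_pairs.append(
            PairSpec(n_true_h + i, TRUE, VERTICAL, int(shapes[k]), int(shapes[k + 1]))
        )
        k += 2

    pseudo_pairs: list[PairSpec] = []
    next_id = n_true_h + n_true_v
    # horizontal pseudo pairs from vertical donors, vertical from horizontal
    for pseudo_orient, donor_orient, n_pseudo in (
        (HORIZONTAL, VERTICAL, n_true_v),
        (VERTICAL, HORIZONTAL, n_true_h),
    ):
        donors = [p for p in true_pairs if p.orientation == donor_orient]
        order = rng.permutation(len(donors))
        for j in range(n_pseudo):
            a = donors[order[j]]
            b = donors[order[(j + 1) % len(donors)]]
            # a contributes its top/left shape, b its bottom/right shape
            pseudo_pairs.append(
                PairSpec(next_id, PSEUDO, pseudo_orient, a.first, b.second)
            )
            next_id += 1

    inv = Inventory(n_true_h, n_true_v, true_pairs, pseudo_pairs, int(seed))
    _validate(inv)
    return inv


def _validate(inv: Inventory) -> None:
    true_shapes = [s for p in inv.true_pairs for s in (p.first, p.second)]
    pseudo_shapes = [s for p in inv.pseudo_pairs for s in (p.first, p.second)]
    if sorted(true_shapes) != sorted(pseudo_shapes):
        raise InvalidInventoryError("pseudo pairs do not partition the shape set")
    if len(set(true_shapes)) != inv.n_shapes:
        raise InvalidInventoryError("shape appears in more than one true pair")
    if len(set(pseudo_shapes)) != inv.n_shapes:
        raise InvalidInventoryError("shape appears in more than one pseudo pair")
    truesets = inv.true_pair_shapesets()
    for p in inv.pseudo_pairs:
        if p.shapes in truesets:
            raise InvalidInventoryError(
                f"pseudo pair {p.pair_id} reproduces a true pair's shape set"
            )


def swap_true_pairs(inv: Inventory, rng: np.random.Generator) -> Inventory:
    """Return a copy of ``inv`` with two shapes exchanged between two randomly
    chosen same-orientation true pairs (same role: first<->first).

    Models a participant who internalized a wrong — but structurally valid —
    inventory. Pseudo pairs are left untouched: the swap describes which
    *objects* the participant believes in.
    """
    orient = HORIZONTAL if rng.random() < 0.5 else VERTICAL
    cands = [p for p in inv.true_pairs if p.orientation == orient]
    i, j = rng.choice(len(cands), size=2, replace=False)
    a, b = cands[int(i)], cands[int(j)]
    new_a = PairSpec(a.pair_id, a.kind, a.orientation, b.first, a.second)
    new_b = PairSpec(b.pair_id, b.kind, b.orientation, a.first, b.second)
    new_true = [
        new_a if p.pair_id == a.pair_id else new_b if p.pair_id == b.pair_id else p
        for p in inv.true_pairs
    ]
    out = Inventory(inv.n_true_h, inv.n_true_v, new_true, list(inv.pseudo_pairs), inv.seed)
    return out
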