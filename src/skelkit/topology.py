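"""The 18-joint skeleton graph emitted by RGB-D body trackers.

The tracker reports 18 named body landmarks per frame.  For estimation the
joints form a tree rooted at the nose: every non-root joint has a single
parent on the chain toward the nose, and the child--parent segments are the
"limbs" whose lengths are treated as rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field


JOINT_NAMES: tuple[str, ...] = (
    "nose",            # 0  (root)
    "chest",           # 1
    "right_shoulder",  # 2
    "right_elbow",     # 3
    "right_wrist",     # 4
    "left_shoulder",   # 5
    "left_elbow",      # 6
    "left_wrist",      # 7
    "right_hip",       # 8
    "right_knee",      # 9
    "right_ankle",     # 10
    "left_hip",        # 11
    "left_knee",       # 12
    "left_ankle",      # 13
    "right_eye",       # 14
    "left_eye",        # 15
    "left_ear",        # 16
    "right_ear",       # 17
)

N_JOINTS = 18

#: joint_id -> parent joint_id (None for the root).  The chest carries both
#: shoulder chains and both hip chains; head joints attach to the nose.
DEFAULT_PARENTS: dict[int, int | None] = {
    0: None,
    1: 0,
    2: 1, 3: 2, 4: 3,
    5: 1, 6: 5, 7: 6,
    8: 1, 9: 8, 10: 9,
    11: 1, 12: 11, 13: 12,
    14: 0, 15: 0, 16: 0, 17: 0,
}

NAME_TO_ID: dict[str, int] = {n: i for i, n in enumerate(JOINT_NAMES)}


class TopologyError(ValueError):
    """Raised when a joint graph violates the skeleton-tree invariants."""


@dataclass(frozen=True)
class SkeletonTopology:
    """Joint identities plus the parent tree rooted at the nose.

    ``limbs`` lists the (child_id, parent_id) segments; every joint except
    the root has exactly one.
    """

    joint_names: tuple[str, ...] = JOINT_NAMES
    parent: dict[int, int | None] = field(
        default_factory=lambda: dict(DEFAULT_PARENTS)
    )

    def __post_init__(self) -> None:
        n = len(self.joint_names)
        if n != N_JOINTS:
            raise TopologyError(f"expected {N_JOINTS} joints, got {n}")
        if set(self.parent) != set(range(n)):
            raise TopologyError("parent map must cover joint ids 0..17 exactly")
        roots = [j for j, p in self.parent.items() if p is None]
        if roots != [0]:
            raise TopologyError(f"root must be joint 0 (nose); found roots {roots}")
        # every joint must reach the root through a finite, acyclic chain
        for j in range(n):
            seen: set[int] = set()
            cur: int | None = j
            while cur is not None:
                if cur in seen:
                    raise TopologyError(f"cycle in parent chain at joint {j}")
                seen.add(cur)
                cur = self.parent[cur]
            if 0 not in seen:
                raise TopologyError(f"joint {j} does not reach the root")

    @property
    def root(self) -> int:
        return 0

    @property
    def limbs(self) -> list[tuple[int, int]]:
        """(child_id, parent_id) pairs, ascending child id; 17 entries."""
        return [(j, p) for j, p in sorted(self.parent.items()) if p is not None]

    def joint_id(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"unknown joint name {name!r}") from None

    def name(self, joint_id: int) -> str:
        return self.joint_names[joint_id]


DEFAULT_TOPOLOGY = SkeletonTopology()
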