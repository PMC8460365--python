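"""Minimal independent BVH parser used to validate exported motion files.

Intentionally shares no code with the package's writer: a plain token
stream parser for the HIERARCHY section and a float table for MOTION.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class BvhJoint:
    name: str
    parent: str | None
    offset: tuple[float, float, float]
    channels: list[str] = field(default_factory=list)


@dataclass
class BvhFile:
    joints: list[BvhJoint]
    frame_time: float
    frames: list[list[float]]

    def channel_columns(self) -> list[str]:
        cols = []
        for j in self.joints:
            cols += [f"{j.name}.{c}" for c in j.channels]
        return cols

    def channel(self, joint: str, chan: str) -> list[float]:
        idx = self.channel_columns().index(f"{joint}.{chan}")
        return [row[idx] for row in self.frames]


def parse_bvh(text: str) -> BvhFile:
    tokens = text.split()
    pos = 0

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def expect(value: str) -> None:
        tok = take()
        if tok != value:
            raise ValueError(f"expected {value!r}, got {tok!r}")

    expect("HIERARCHY")
    joints: list[BvhJoint] = []
    stack: list[str] = []

    def parse_joint(kind: str) -> None:
        name = take()
        expect("{")
        parent = stack[-1] if stack else None
        stack.append(name)
        joint = BvhJoint(name, parent, (0.0, 0.0, 0.0))
        joints.append(joint)
        while True:
            tok = take()
            if tok == "OFFSET":
                joint.offset = (float(take()), float(take()), float(take()))
            elif tok == "CHANNELS":
                n = int(take())
                joint.channels = [take() for _ in range(n)]
            elif tok == "JOINT":
                parse_joint("JOINT")
            elif tok == "End":
                expect("Site")
                expect("{")
                expect("OFFSET")
                take(), take(), take()
                expect("}")
            elif tok == "}":
                stack.pop()
                return
            else:
                raise ValueError(f"unexpected token {tok!r} in {name}")

    expect("ROOT")
    parse_joint("ROOT")
    expect("MOTION")
    expect("Frames:")
    n_frames = int(take())
    expect("Frame")
    expect("Time:")
    frame_time = float(take())
    n_chan = sum(len(j.channels) for j in joints)
    frames = []
    for _ in range(n_frames):
        frames.append([float(take()) for _ in range(n_chan)])
    if pos != len(tokens):
        raise ValueError("trailing data after MOTION frames")
    return BvhFile(joints, frame_time, frames)
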