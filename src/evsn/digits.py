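"""Digit bitmaps for the jittered-pattern experiment, with plain-PBM I/O.

Digits 1-9 are rendered as seven-segment binary masks.  Under random
jitter the stimulus carries essentially spatial information only, so the
exact glyph style is immaterial; seven-segment shapes keep the masks
simple, distinct and easy to regenerate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["digit_bitmap", "read_pbm", "write_pbm"]

# segments: a=top, b=top-right, c=bottom-right, d=bottom, e=bottom-left,
# f=top-left, g=middle
_SEGMENTS = {
    1: "bc",
    2: "abged",
    3: "abgcd",
    4: "fgbc",
    5: "afgcd",
    6: "afgedc",
    7: "abc",
    8: "abcdefg",
    9: "abcdfg",
}


def digit_bitmap(digit: int, height: int = 24, thickness: int = 3) -> np.ndarray:
    """Binary ``(height, width)`` mask of a seven-segment digit 1-9."""
    if digit not in _SEGMENTS:
        raise ValueError("digit must be in 1..9")
    h = height
    w = (h + 1) // 2
    t = thickness
    mid0 = (h - t) // 2
    m = np.zeros((h, w), dtype=bool)
    segs = _SEGMENTS[digit]
    if "a" in segs:
        m[:t, :] = True
    if "d" in segs:
        m[-t:, :] = True
    if "g" in segs:
        m[mid0 : mid0 + t, :] = True
    if "b" in segs:
        m[: mid0 + t, -t:] = True
    if "c" in segs:
        m[mid0:, -t:] = True
    if "f" in segs:
        m[: mid0 + t, :t] = True
    if "e" in segs:
        m[mid0:, :t] = True
    return m


def write_pbm(mask: np.ndarray, path) -> None:
    """Write a binary mask as a plain (P1) PBM file."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"P1\n{w} {h}\n")
        for row in mask.astype(int):
            fh.write(" ".join(map(str, row)) + "\n")


def read_pbm(path) -> np.ndarray:
    """Read a plain (P1) PBM file into a boolean mask."""
    with open(path, "r", encoding="ascii") as fh:
        tokens: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path} is not a plain PBM (P1) file")
    w, h = int(tokens[1]), int(tokens[2])
    bits = np.array(tokens[3 : 3 + w * h], dtype=int)
    if bits.size != w * h:
        raise ValueError(f"{path}: expected {w * h} pixels, found {bits.size}")
    return bits.reshape(h, w).astype(bool)
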