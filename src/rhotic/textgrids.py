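"""Minimal Praat TextGrid (long text format) reading and writing.

Only interval tiers are supported, which is all a forced-alignment interval
file needs here. The writer emits the canonical long format that Praat and
other TextGrid tools read back; the reader accepts the same format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import DataError


@dataclass
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[Interval] = field(default_factory=list)

    def labeled(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.text.strip()]


@dataclass
class TextGrid:
    xmin: float
    xmax: float
    tiers: list[IntervalTier] = field(default_factory=list)

    def tier(self, name: str) -> IntervalTier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise DataError(f"TextGrid has no tier named {name!r}")


def write_textgrid(grid: TextGrid, path) -> None:
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {grid.xmin:.6f}",
        f"xmax = {grid.xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(grid.tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(grid.tiers, start=1):
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{tier.name}"',
            f"        xmin = {tier.xmin:.6f}",
            f"        xmax = {tier.xmax:.6f}",
            f"        intervals: size = {len(tier.intervals)}",
        ]
        for ii, iv in enumerate(tier.intervals, start=1):
            text = iv.text.replace('"', '""')
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {iv.xmin:.6f}",
                f"            xmax = {iv.xmax:.6f}",
                f'            text = "{text}"',
            ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_NUM = re.compile(r"=\s*([-\d.eE+]+)")
_STR = re.compile(r'=\s*"(.*)"\s*$')


def _num(line: str) -> float:
    m = _NUM.search(line)
    if m is None:
        raise DataError(f"expected a number in TextGrid line: {line!r}")
    return float(m.group(1))


def _text(line: str) -> str:
    m = _STR.search(line)
    if m is None:
        raise DataError(f"expected a string in TextGrid line: {line!r}")
    return m.group(1).replace('""', '"')


def read_textgrid(path) -> TextGrid:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not any("TextGrid" in ln for ln in lines[:3]):
        raise DataError(f"{path}: not a TextGrid file")
    grid = TextGrid(xmin=_num(lines[2]), xmax=_num(lines[3]))
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("class") and "IntervalTier" in ln:
            tier = IntervalTier(
                name=_text(lines[i + 1]),
                xmin=_num(lines[i + 2]),
                xmax=_num(lines[i + 3]),
            )
            n = int(_num(lines[i + 4]))
            i += 5
            for _ in range(n):
                # each interval block: header, xmin, xmax, text
                if lines[i].startswith("intervals ["):
                    i += 1
                iv = Interval(xmin=_num(lines[i]), xmax=_num(lines[i + 1]), text=_text(lines[i + 2]))
                tier.intervals.append(iv)
                i += 3
            grid.tiers.append(tier)
        else:
            i += 1
    return grid
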