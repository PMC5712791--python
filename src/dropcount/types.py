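"""Shared light-weight containers for detected droplets.

Conventions used across the package:

* images are 2-D ``float64`` numpy arrays with intensities in ``[0, 1]``
  (8- or 16-bit sources are normalized on read by their bit-depth maximum);
* binary maps are 2-D boolean arrays of the same shape as their source;
* circle coordinates are 0-based ``(row, col)`` pixel positions with row
  increasing downward, radii in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Circle:
    """A detected micro-droplet: center ``(row, col)``, radius, vote score.

    ``score`` is the fraction-of-perimeter support the circle received in the
    Hough accumulator (1.0 for a complete ideal circle); circles that come
    from ground truth rather than detection carry ``score=1.0``.
    """

    row: float
    col: float
    radius: float
    score: float = 1.0
    fluorescent: bool = False

    def center_distance(self, other: "Circle") -> float:
        return float(np.hypot(self.row - other.row, self.col - other.col))


@dataclass
class CircleSet:
    """An ordered collection of circles for one image.

    Iteration order is deterministic: sorted by ``(row, col)``.
    """

    circles: list[Circle] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.circles = sorted(self.circles, key=lambda c: (c.row, c.col))

    def __len__(self) -> int:
        return len(self.circles)

    def __iter__(self) -> Iterator[Circle]:
        return iter(self.circles)

    def __getitem__(self, i: int) -> Circle:
        return self.circles[i]

    @property
    def n_fluorescent(self) -> int:
        return sum(c.fluorescent for c in self.circles)

    def with_flags(self, flags: Sequence[bool]) -> "CircleSet":
        if len(flags) != len(self.circles):
            raise ValueError("one flag per circle required")
        return CircleSet(
            [replace(c, fluorescent=bool(f)) for c, f in zip(self.circles, flags)]
        )

    def to_dataframe(self, image: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image": [image] * len(self.circles),
                "row": [c.row for c in self.circles],
                "col": [c.col for c in self.circles],
                "radius": [c.radius for c in self.circles],
                "fluorescent": [bool(c.fluorescent) for c in self.circles],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CircleSet":
        return cls(
            [
                Circle(
                    row=float(r.row),
                    col=float(r.col),
                    radius=float(r.radius),
                    fluorescent=bool(r.fluorescent),
                )
                for r in df.itertuples(index=False)
            ]
        )
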