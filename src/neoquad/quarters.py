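"""Calendar quarters: the analysis unit for the quarterly life tables."""

from __future__ import annotations

from typing import Iterator, NamedTuple

import pandas as pd


class Quarter(NamedTuple):
    """A calendar quarter, e.g. ``Quarter(2010, 4)`` = Oct-Dec 2010."""

    year: int
    q: int

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(year=self.year, month=3 * (self.q - 1) + 1, day=1)

    @property
    def end(self) -> pd.Timestamp:
        """Exclusive upper bound: first instant of the next quarter."""
        return self.next().start

    def next(self) -> "Quarter":
        if self.q == 4:
            return Quarter(self.year + 1, 1)
        return Quarter(self.year, self.q + 1)

    @classmethod
    def of(cls, ts: pd.Timestamp) -> "Quarter":
        return cls(ts.year, (ts.month - 1) // 3 + 1)

    @classmethod
    def parse(cls, text: str) -> "Quarter":
        year, q = text.split("Q")
        quarter = cls(int(year), int(q))
        if quarter.q not in (1, 2, 3, 4):
            raise ValueError(f"invalid quarter index in {text!r}")
        return quarter


def quarter_range(start: Quarter, n: int) -> list[Quarter]:
    """``n`` consecutive quarters beginning at ``start``."""
    out: list[Quarter] = []
    cur = start
    for _ in range(n):
        out.append(cur)
        cur = cur.next()
    return out


def iter_quarters(start: Quarter, end: Quarter) -> Iterator[Quarter]:
    """Quarters from ``start`` to ``end`` inclusive."""
    cur = start
    while cur <= end:
        yield cur
        cur = cur.next()
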