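"""Sliding-window smoothing of the per-site ΔSNP index.

Windows are anchored at coordinate 0 of each chromosome, advanced by a
fixed step, and clipped (never dropped) at the chromosome end.  The
windowed statistic is the unweighted arithmetic mean of the ΔSNP index of
the member sites; a 1-based site position ``p`` belongs to the 0-based
half-open window ``[a, b)`` iff ``a <= p - 1 < b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stats import SnpIndexRecord

__all__ = ["WindowSpec", "WindowStat", "make_windows", "window_means"]


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry. Defaults: 25-kb windows advanced in 5-kb steps."""

    size: int = 25_000
    step: int = 5_000

    def __post_init__(self) -> None:
        if not (self.size >= self.step >= 1):
            raise ValueError(f"need size >= step >= 1, got size={self.size} step={self.step}")


@dataclass(frozen=True)
class WindowStat:
    """One window's mean ΔSNP index plus its null band and call.

    ``start``/``end`` are 0-based half-open.  ``mean_delta`` is ``None``
    for empty windows; ``band_lo``/``band_hi`` are filled by the null-band
    stage (``band_lo`` may be ``-inf`` for upper-only calls).
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_delta: float | None
    band_lo: float | None = None
    band_hi: float | None = None
    significant: bool = False


def make_windows(chrom_length: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Tile ``[0, chrom_length)`` with windows ``[k*step, k*step + size)``.

    One window per ``k = 0, 1, ...`` while ``k*step < chrom_length``; the
    final windows are clipped to the chromosome end.
    """
    if chrom_length < 1:
        raise ValueError("chromosome length must be >= 1")
    out = []
    start = 0
    while start < chrom_length:
        out.append((start, min(start + spec.size, chrom_length)))
        start += spec.step
    return out


def window_means(
    records: Sequence[SnpIndexRecord],
    chrom_lengths: Mapping[str, int],
    spec: WindowSpec = WindowSpec(),
) -> list[WindowStat]:
    """Average the ΔSNP index within every window of every chromosome.

    ``records`` may arrive unsorted; they are sorted by (chrom, pos).
    Chromosomes present in ``chrom_lengths`` but without any site still
    contribute (empty) windows, so the scan output covers the genome.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    by_chrom: dict[str, list[SnpIndexRecord]] = {}
    for r in recs:
        by_chrom.setdefault(r.chrom, []).append(r)

    stats: list[WindowStat] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        chrom_recs = by_chrom.get(chrom, [])
        pos0 = np.array([r.pos - 1 for r in chrom_recs], dtype=np.int64)
        delta = np.array([r.delta for r in chrom_recs], dtype=float)
        for start, end in make_windows(length, spec):
            lo = int(np.searchsorted(pos0, start, side="left"))
            hi = int(np.searchsorted(pos0, end, side="left"))
            n = hi - lo
            mean = float(np.sum(delta[lo:hi])) / n if n else None
            stats.append(WindowStat(chrom=chrom, start=start, end=end, n_sites=n, mean_delta=mean))
    return stats


def window_members(
    records: Sequence[SnpIndexRecord], window: WindowStat
) -> list[SnpIndexRecord]:
    """The records falling in one window (membership rule as above)."""
    return [
        r
        for r in records
        if r.chrom == window.chrom and window.start <= r.pos - 1 < window.end
    ]
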