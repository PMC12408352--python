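"""Monte-Carlo confidence bands for the windowed ΔSNP index.

Under the no-linkage null in an F2-type design, the mutant allele at an
unlinked site sits at frequency ½ in both bulks, up to two layers of
sampling noise: which chromosomes entered each bulk (binomial over
``2 × bulk size`` gametes) and which reads sampled each pool (binomial over
the observed depth).  The null distribution of a window's mean Δ is built
by replaying exactly those two layers at the observed depths.

A window spans far less than a centimorgan, so within one replicate a
single bulk-frequency pair ``(f_mut, f_wt)`` is shared by every site in the
window — sites 25 kb apart are effectively completely linked, and treating
them as independent would understate the null variance of the window mean.

Significance is pointwise ("is this window's mean outside the 1−α band"),
matching the single-window criterion such scans usually report; a
genome-wide max-statistic band is available via ``genome_wide=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .simulate import CrossDesign
from .stats import SnpIndexRecord
from .windows import WindowStat

__all__ = ["BandSpec", "simulate_null_window", "confidence_band", "flag_windows"]

SIDEDNESS = ("two_sided_band", "upper_only")


@dataclass(frozen=True)
class BandSpec:
    """Null-band construction parameters.

    alpha
        Pointwise significance level (default 0.01).
    n_sims
        Monte-Carlo replicates per window (default 10,000; at least 100).
    sidedness
        ``two_sided_band`` (default) flags |signal| in either tail, the
        natural choice for plotting bands; ``upper_only`` flags only
        mutant-pool excess, the one-sided peak call.
    genome_wide
        If set, one shared band from the null distribution of the
        genome-wide *maximum* window mean (max-statistic correction).
    """

    alpha: float = 0.01
    n_sims: int = 10_000
    sidedness: str = "two_sided_band"
    seed: int = 0
    genome_wide: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100 for a usable empirical quantile")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")


def simulate_null_window(
    depths_mut: Sequence[int],
    depths_wt: Sequence[int],
    design: CrossDesign,
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of one window's mean Δ at the observed depths.

    Per replicate: draw one bulk frequency per pool for the whole window,
    ``f = X / (2N)`` with ``X ~ Binomial(2N, ½)``; then per site draw
    mutant-read counts ``Binomial(depth, f)`` in each pool, form the
    per-site Δ and average across the window.  Returns ``n_sims`` means.
    """
    d_mut = np.asarray(depths_mut, dtype=np.int64)
    d_wt = np.asarray(depths_wt, dtype=np.int64)
    if d_mut.size == 0 or d_mut.size != d_wt.size:
        raise ValueError("window must contain >= 1 site with depths for both pools")
    if (d_mut <= 0).any() or (d_wt <= 0).any():
        raise ValueError("all per-site depths must be > 0 (filter uncovered sites)")

    two_n_mut = 2 * design.mut_bulk_size
    two_n_wt = 2 * design.wt_bulk_size
    f_mut = rng.binomial(two_n_mut, 0.5, size=n_sims) / two_n_mut
    f_wt = rng.binomial(two_n_wt, 0.5, size=n_sims) / two_n_wt

    alt_mut = rng.binomial(d_mut[None, :], f_mut[:, None])
    alt_wt = rng.binomial(d_wt[None, :], f_wt[:, None])
    delta = alt_mut / d_mut[None, :] - alt_wt / d_wt[None, :]
    return delta.mean(axis=1)


def _nearest_rank(sorted_sample: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q·n)-th order statistic."""
    n = sorted_sample.size
    k = max(1, int(np.ceil(q * n)))
    return float(sorted_sample[min(k, n) - 1])


def confidence_band(
    null_means: np.ndarray, alpha: float, sidedness: str = "two_sided_band"
) -> tuple[float, float]:
    """Empirical 1−α band from simulated null window means.

    Nearest-rank quantiles (no interpolation, reproducible everywhere):
    two-sided uses the α/2 and 1−α/2 quantiles; upper-only returns
    ``(-inf, q(1−α))``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    x = np.sort(np.asarray(null_means, dtype=float))
    if x.size < 100:
        raise ValueError("need >= 100 simulated means for a quantile band")
    if sidedness == "two_sided_band":
        return _nearest_rank(x, alpha / 2.0), _nearest_rank(x, 1.0 - alpha / 2.0)
    return float("-inf"), _nearest_rank(x, 1.0 - alpha)


def flag_windows(
    windows: Sequence[WindowStat],
    records: Sequence[SnpIndexRecord],
    design: CrossDesign,
    spec: BandSpec = BandSpec(),
) -> list[WindowStat]:
    """Fill bands and significance flags on a set of windows.

    Empty windows keep missing bands and are never significant.  A window
    is significant when its observed mean Δ falls strictly outside the
    band.  Each window gets an independent child random stream spawned
    from ``spec.seed``, so results are deterministic and independent of
    evaluation order.

    ``records`` must be the same per-site records the windows were
    computed from (their depths drive the read-resampling layer).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    for chrom in {r.chrom for r in recs}:
        sub = [r for r in recs if r.chrom == chrom]
        by_chrom[chrom] = (
            np.array([r.pos - 1 for r in sub], dtype=np.int64),
            np.array([r.depth_mut for r in sub], dtype=np.int64),
            np.array([r.depth_wt for r in sub], dtype=np.int64),
        )

    children = np.random.SeedSequence(spec.seed).spawn(len(windows))
    out: list[WindowStat] = []
    null_means_all: list[np.ndarray | None] = []
    for w, child in zip(windows, children):
        if w.n_sites == 0:
            null_means_all.append(None)
            continue
        if w.chrom not in by_chrom:
            raise ValueError(
                f"{w.chrom}:[{w.start},{w.end}): window says {w.n_sites} sites but no "
                "records for that chromosome; pass the records the windows came from"
            )
        pos0, d_mut, d_wt = by_chrom[w.chrom]
        lo = int(np.searchsorted(pos0, w.start, side="left"))
        hi = int(np.searchsorted(pos0, w.end, side="left"))
        if hi - lo != w.n_sites:
            raise ValueError(
                f"{w.chrom}:[{w.start},{w.end}): window says {w.n_sites} sites "
                f"but records contain {hi - lo}; pass the records the windows came from"
            )
        rng = np.random.default_rng(child)
        null_means_all.append(
            simulate_null_window(d_mut[lo:hi], d_wt[lo:hi], design, spec.n_sims, rng)
        )

    if spec.genome_wide:
        stacked = [m for m in null_means_all if m is not None]
        if stacked:
            arr = np.stack(stacked)  # (n_windows, n_sims)
            max_means = arr.max(axis=0)
            min_means = arr.min(axis=0)
            if spec.sidedness == "two_sided_band":
                shared_lo = _nearest_rank(np.sort(min_means), spec.alpha / 2.0)
                shared_hi = _nearest_rank(np.sort(max_means), 1.0 - spec.alpha / 2.0)
            else:
                shared_lo = float("-inf")
                shared_hi = _nearest_rank(np.sort(max_means), 1.0 - spec.alpha)

    for w, null_means in zip(windows, null_means_all):
        if null_means is None:
            out.append(replace(w, band_lo=None, band_hi=None, significant=False))
            continue
        if spec.genome_wide:
            band_lo, band_hi = shared_lo, shared_hi
        else:
            band_lo, band_hi = confidence_band(null_means, spec.alpha, spec.sidedness)
        mean = w.mean_delta
        sig = mean > band_hi or (spec.sidedness == "two_sided_band" and mean < band_lo)
        out.append(replace(w, band_lo=band_lo, band_hi=band_hi, significant=bool(sig)))
    return out
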