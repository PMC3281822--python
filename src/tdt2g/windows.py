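"""Sliding-window association scan and per-marker aggregation.

A scan tests every window of a fixed width (offset 1 marker by default) and,
for plotting against marker position, averages the p-values of all windows
covering each marker.  Each window's holdout split uses a seed derived from
the master seed and the window start, so extending the panel never reshuffles
existing windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .datasets import TrioDataset
from .haplotype_core import count_transmissions, phase_dataset
from .tdt_tests import TestResult, tdt_max, tdt_mhet, tdt_single
from .two_groups import MaxTest, MhetTest, TwoGroupsTest, holdout_wrap


@dataclass(frozen=True)
class WindowSpec:
    """A window of ``width`` consecutive markers starting at a 0-based index."""

    start: int
    width: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.width < 1:
            raise ValueError("start must be >= 0 and width >= 1")

    @property
    def stop(self) -> int:
        return self.start + self.width


def sliding_windows(n_markers: int, width: int, offset: int = 1) -> List[WindowSpec]:
    """All windows of ``width`` markers at starts 0, offset, 2*offset, ...

    count = floor((n_markers - width) / offset) + 1.
    """
    if not 1 <= width <= n_markers:
        raise ValueError("need 1 <= width <= n_markers")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    return [WindowSpec(s, width) for s in range(0, n_markers - width + 1, offset)]


def window_seed(master_seed: int, start: int) -> int:
    """Per-window seed: mixes the master seed with the window start so each
    window's split is independent yet reproducible."""
    return int((master_seed ^ (start * 0x9E3779B1)) & 0x7FFFFFFF)


_HOLDOUT_BASES = {"2g": TwoGroupsTest, "mhet": MhetTest, "max": MaxTest}


def _plain_single(trios: TrioDataset, window) -> TestResult:
    txs, _ = phase_dataset(trios, window)
    table = count_transmissions(txs)
    haps = table.haplotypes
    if len(haps) < 2:
        return tdt_single(0, 0)
    b = table.t(haps[0])
    c = table.u(haps[0])
    return tdt_single(b, c)


def _plain_stat(name: str) -> Callable:
    fn = {"mhet": tdt_mhet, "max": tdt_max}[name]

    def run(trios: TrioDataset, window) -> TestResult:
        txs, _ = phase_dataset(trios, window)
        return fn(count_transmissions(txs))

    return run


def scan(
    trios: TrioDataset,
    test: str = "2g",
    width: int = 1,
    fraction: float = 0.5,
    seed: int = 0,
    offset: int = 1,
    holdout: bool = True,
    n_markers: Optional[int] = None,
) -> List[TestResult]:
    """Run one test over every sliding window of the panel.

    ``test`` is one of ``2g``, ``mhet``, ``max`` (each holdout or plain) or
    ``tdt1`` (classic single-marker TDT; requires width 1).  Windows with no
    informative genotypes carry p = 1 and a flag but never abort the scan.
    """
    n = n_markers if n_markers is not None else trios.n_markers
    results: List[TestResult] = []
    for w in sliding_windows(n, width, offset):
        window = (w.start, w.stop)
        if test == "tdt1":
            if width != 1:
                raise ValueError("tdt1 is a single-marker test; use width 1")
            res = _plain_single(trios, window).with_context(window=window)
        elif test in _HOLDOUT_BASES:
            if holdout or test == "2g":
                wseed = window_seed(seed, w.start)
                res = holdout_wrap(
                    _HOLDOUT_BASES[test](), trios, window, fraction, wseed
                )
            else:
                res = _plain_stat(test)(trios, window).with_context(window=window)
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(res)
    return results


def per_marker_aggregate(
    results: Sequence[TestResult],
    n_markers: int,
    method: str = "mean",
) -> np.ndarray:
    """Average, per marker, the p-values of all windows covering it.

    ``method`` is the arithmetic ``mean`` (default) or ``geometric`` mean.
    Markers covered by no window get NaN.
    """
    if method not in ("mean", "geometric"):
        raise ValueError("method must be 'mean' or 'geometric'")
    sums = np.zeros(n_markers)
    counts = np.zeros(n_markers, dtype=int)
    for r in results:
        if r.window is None:
            raise ValueError("result lacks window coordinates")
        start, stop = r.window
        p = np.log(max(r.p_value, 1e-300)) if method == "geometric" else r.p_value
        sums[start:stop] += p
        counts[start:stop] += 1
    with np.errstate(invalid="ignore"):
        out = sums / counts
    if method == "geometric":
        out = np.exp(out)
    out[counts == 0] = np.nan
    return out
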