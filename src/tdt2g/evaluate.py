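"""Replicate-level harnesses: association rates, type-I error tables under
stratification, power/specificity curves, reproducibility and missing-data
summaries.

Every rate carries an exact binomial confidence interval and stochastic
checks are phrased as interval inclusions, never point equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom, binomtest

from .datasets import TrioDataset
from .haplotype_core import Window
from .simulate import (
    DiseaseModel,
    PoolSimConfig,
    StratificationConfig,
    inject_missing,
    reproducibility_pair,
    simulate_disease_trios,
    simulate_stratified_null,
)
from .two_groups import (
    BaseTest,
    MhetTest,
    TwoGroupsTest,
    cross_sample_test,
    holdout_split,
    holdout_wrap,
)


@dataclass(frozen=True)
class RateEstimate:
    """An association rate over replicate datasets with its exact 95% CI."""

    rate: float
    n_replicates: int
    alpha: float
    ci95: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.ci95[0] - 1e-12 <= self.rate <= self.ci95[1] + 1e-12):
            raise ValueError("ci95 must contain the rate")


def association_rate(p_values: Sequence[float], alpha: float) -> RateEstimate:
    """Fraction of replicates with p <= alpha, with exact binomial 95% CI."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    k = int((p <= alpha).sum())
    ci = binomtest(k, p.size).proportion_ci(confidence_level=0.95, method="exact")
    return RateEstimate(k / p.size, int(p.size), alpha, (float(ci.low), float(ci.high)))


def null_rate_band(alpha: float, n: int, confidence: float = 0.99) -> Tuple[float, float]:
    """Central exact-binomial band for an empirical rate when the true
    rejection probability is the nominal ``alpha``."""
    tail = (1.0 - confidence) / 2.0
    return (
        float(binom.ppf(tail, n, alpha)) / n,
        float(binom.ppf(1.0 - tail, n, alpha)) / n,
    )


def paired_rate_band(
    flags_a: Sequence[bool], flags_b: Sequence[bool], confidence: float = 0.95
) -> Tuple[float, float]:
    """Difference of two paired rejection rates and its Monte-Carlo band.

    Returns ``(rate_a - rate_b, halfwidth)`` where the halfwidth is the
    normal-approximation bound on the paired difference, floored at one
    replicate (1/n) so a zero empirical variance never collapses the band.
    """
    a = np.asarray(flags_a, dtype=float)
    b = np.asarray(flags_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    d = a - b
    z = {0.95: 1.959964, 0.99: 2.575829}.get(confidence)
    if z is None:
        from scipy.stats import norm

        z = float(norm.ppf(1 - (1 - confidence) / 2))
    half = max(z * d.std(ddof=1) / np.sqrt(n), 1.0 / n)
    return float(d.mean()), float(half)


def _replicate_seeds(
    master_seed: int, tag: Sequence[int], reps: int, streams: int = 1
) -> np.ndarray:
    """Stable per-replicate seeds keyed by the study configuration.

    ``streams`` independent seeds are drawn per replicate (shape
    ``(reps, streams)``) so that e.g. dataset simulation and the holdout
    split never share a generator state — reusing one seed for both would
    couple the split to the founder draws.
    """
    ss = np.random.SeedSequence([int(master_seed)] + [int(t) for t in tag])
    out = (ss.generate_state(reps * streams) % (2**31)).astype(np.int64)
    return out.reshape(reps, streams)


def replicate_pvalues(
    make_dataset: Callable[[int], TrioDataset],
    reps: int,
    seed: int,
    tag: Sequence[int] = (),
    base: Optional[BaseTest] = None,
    window: Optional[Window] = None,
    fraction: float = 0.5,
) -> np.ndarray:
    """Holdout-test p-values over ``reps`` independently simulated datasets."""
    base = base or TwoGroupsTest()
    seeds = _replicate_seeds(seed, tag, reps, streams=2)
    out = np.empty(reps)
    for i, (data_seed, split_seed) in enumerate(seeds):
        ds = make_dataset(int(data_seed))
        w = window if window is not None else (0, ds.n_markers)
        out[i] = holdout_wrap(base, ds, w, fraction, int(split_seed)).p_value
    return out


def type1_table(
    qs: Sequence[float],
    pps: Sequence[float],
    alphas: Sequence[float] = (0.01, 0.05),
    l: int = 1,
    reps: int = 1000,
    n_families: int = 500,
    seed: int = 0,
    base: Optional[BaseTest] = None,
) -> pd.DataFrame:
    """Type-I error rates of the holdout test under stratification/admixture.

    One row per (alpha, q, pp, l) cell; each (q, pp) cell shares its ``reps``
    simulated null datasets across the nominal levels, as a published table
    would.  Deterministic for a fixed seed and cell, regardless of grid shape.
    """
    rows = []
    for q in qs:
        for pp in pps:
            tag = (int(round(q * 1000)), int(round(pp * 1000)), l, n_families)

            def make(s: int, q=q, pp=pp) -> TrioDataset:
                return simulate_stratified_null(
                    StratificationConfig(
                        n_families=n_families, pp=pp, q=q, l=l, theta=0.5, seed=s
                    )
                )

            pvals = replicate_pvalues(make, reps, seed, tag=tag, base=base)
            for alpha in alphas:
                est = association_rate(pvals, alpha)
                rows.append(
                    {
                        "alpha": alpha, "q": q, "pp": pp, "l": l,
                        "rate": est.rate, "ci_lo": est.ci95[0], "ci_hi": est.ci95[1],
                        "n_replicates": reps,
                    }
                )
    return pd.DataFrame(rows)


def power_curve(
    theta_grid: Sequence[float],
    pool,
    model: DiseaseModel,
    l: int = 8,
    reps: int = 100,
    n_families: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
    base: Optional[BaseTest] = None,
) -> pd.DataFrame:
    """Association rate of the holdout test as a function of the
    marker-to-disease-locus recombination fraction.

    theta = 0 measures power, theta = 0.5 locus specificity (type-I error).
    """
    rows = []
    for theta in theta_grid:
        tag = (int(round(theta * 10000)), l, n_families, int(round(model.rr * 100)))

        def make(s: int, theta=theta) -> TrioDataset:
            return simulate_disease_trios(
                PoolSimConfig(
                    pool=pool, n_families=n_families, l=l, theta=theta,
                    model=model, seed=s,
                )
            )

        pvals = replicate_pvalues(make, reps, seed, tag=tag, base=base)
        est = association_rate(pvals, alpha)
        rows.append(
            {
                "theta": theta, "rate": est.rate,
                "ci_lo": est.ci95[0], "ci_hi": est.ci95[1], "n_replicates": reps,
            }
        )
    return pd.DataFrame(rows)


def reproducibility_rates(
    population_sampler: Callable[[int], TrioDataset],
    window: Window,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired first/second-dataset rejection indicators for the
    reproducibility study.

    Per replicate two independent datasets A and B are drawn and five
    protocols are scored (one indicator column each):

    * ``mhet_plain_first``   — mhet computed wholly on A;
    * ``mhet_plain_second``  — A's haplotype model scored on B;
    * ``mhet_holdout_second``— mhet fit on A's training half, scored on the
      matching half of B;
    * ``tg_first``           — 2G holdout within A (fit half A1, score A2);
    * ``tg_second``          — the same fitted groups (A1) scored on B's
      matching half.

    ``tg_first``/``tg_second`` share the fitted model and the scored sample
    size, so their paired difference isolates pure sampling variation — the
    sample-reproducibility property.
    """
    mhet = MhetTest()
    tg = TwoGroupsTest()
    seeds = _replicate_seeds(seed, (3,), reps, streams=2)
    rows = []
    for pair_seed, split_seed in seeds:
        a, b = reproducibility_pair(population_sampler, int(pair_seed))
        a1, a2 = holdout_split(a, 0.5, int(split_seed))
        b1, _ = holdout_split(b, 0.5, int(split_seed))
        rows.append(
            {
                "mhet_plain_first": cross_sample_test(mhet, a, a, window).p_value <= alpha,
                "mhet_plain_second": cross_sample_test(mhet, a, b, window).p_value <= alpha,
                "mhet_holdout_second": cross_sample_test(mhet, a1, b1, window).p_value <= alpha,
                "tg_first": cross_sample_test(tg, a1, a2, window).p_value <= alpha,
                "tg_second": cross_sample_test(tg, a1, b1, window).p_value <= alpha,
            }
        )
    return pd.DataFrame(rows)


def missing_data_rates(
    make_dataset: Callable[[int], TrioDataset],
    proportions: Sequence[float],
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    window: Optional[Window] = None,
    base: Optional[BaseTest] = None,
) -> pd.DataFrame:
    """Rejection rate of the holdout test after injecting missing parental
    genotype cells at each proportion.

    Proportions are coupled per replicate: one complete dataset and one cell
    permutation are drawn, and each proportion deletes a nested prefix of the
    permutation, so the rate differences across proportions are paired
    comparisons free of between-replicate noise."""
    base = base or TwoGroupsTest()
    seeds = _replicate_seeds(seed, (7,), reps, streams=3)
    flags: Dict[float, List[bool]] = {p: [] for p in proportions}
    for data_seed, cell_seed, split_seed in seeds:
        complete = make_dataset(int(data_seed))
        w = window if window is not None else (0, complete.n_markers)
        n_cells = 2 * len(complete) * complete.n_markers
        perm = np.random.default_rng(int(cell_seed)).permutation(n_cells)
        for prop in proportions:
            ds = inject_missing(complete, prop, _cells=perm)
            flags[prop].append(
                holdout_wrap(base, ds, w, 0.5, int(split_seed)).p_value <= alpha
            )
    rows = []
    for prop in proportions:
        k = int(sum(flags[prop]))
        ci = binomtest(k, reps).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            {
                "proportion": prop,
                "rate": k / reps,
                "ci_lo": float(ci.low),
                "ci_hi": float(ci.high),
                "n_replicates": reps,
                "flags": np.array(flags[prop]),
            }
        )
    return pd.DataFrame(rows)
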