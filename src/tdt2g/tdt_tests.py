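"""Comparison TDT statistics: classic biallelic TDT, the H-1-df multimarker
heterozygosity TDT (``mhet``), and the max one-vs-rest TDT (``max``).

All three compare transmission against nontransmission counts from
heterozygous parents of affected children.  The classic TDT is a McNemar
chi-square on the two discordant allele counts.  ``mhet`` sums per-haplotype
McNemar terms over all H distinct haplotypes, scaled by (H-1)/H, and is
asymptotically chi-square with H-1 df under no linkage.  ``max`` takes the
largest one-vs-rest biallelic TDT over haplotypes; its plain form does not
follow a chi-square under the null, so only a Bonferroni bound on the p-value
is reported (the honest 1-df version selects the haplotype on a training
subset, see :func:`tdt2g.two_groups.holdout_wrap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from scipy.stats import chi2

from .haplotype_core import Haplotype, TransmissionTable

NO_INFORMATIVE = "no informative genotypes"
BONFERRONI_BOUND = "bonferroni bound"
UNTESTABLE = "untestable"


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test on one window."""

    statistic: float
    df: int
    p_value: float
    n_informative: int
    test_name: str
    window: Optional[Tuple[int, int]] = None  # 0-based half-open marker range
    seed: Optional[int] = None
    flags: Tuple[str, ...] = field(default_factory=tuple)

    def with_context(
        self,
        window: Optional[Tuple[int, int]] = None,
        seed: Optional[int] = None,
    ) -> "TestResult":
        from dataclasses import replace

        return replace(self, window=window if window is not None else self.window,
                       seed=seed if seed is not None else self.seed)


def _chi2_result(
    stat: float, df: int, n: int, name: str, flags: Tuple[str, ...] = ()
) -> TestResult:
    p = float(chi2.sf(stat, df)) if n > 0 else 1.0
    return TestResult(stat, df, p, n, name, flags=flags)


def tdt_single(b: int, c: int) -> TestResult:
    """Classic biallelic TDT: (b-c)^2/(b+c) on the discordant transmission
    counts of the two alleles, chi-square 1 df."""
    if b < 0 or c < 0:
        raise ValueError("counts must be nonnegative")
    n = b + c
    if n == 0:
        return TestResult(0.0, 1, 1.0, 0, "tdt1", flags=(NO_INFORMATIVE,))
    stat = (b - c) ** 2 / n
    return _chi2_result(stat, 1, n, "tdt1")


def tdt_mhet(table: TransmissionTable, df: Optional[int] = None) -> TestResult:
    """Multimarker heterozygosity TDT over all distinct haplotypes.

    statistic = (H-1)/H * sum_i (T_i - U_i)^2 / (T_i + U_i), df = H - 1.
    ``df`` may be pinned by a holdout wrapper when the haplotype set was fixed
    on a training subset (H then counts the training haplotypes).
    """
    H = (df + 1) if df is not None else table.n_distinct
    if H < 2:
        return TestResult(0.0, 1, 1.0, table.n_informative, "mhet", flags=(UNTESTABLE,))
    total = 0.0
    for h in table.haplotypes:
        t, u = table.t(h), table.u(h)
        if t + u > 0:
            total += (t - u) ** 2 / (t + u)
    stat = (H - 1) / H * total
    if table.n_informative == 0:
        return TestResult(0.0, H - 1, 1.0, 0, "mhet", flags=(NO_INFORMATIVE,))
    return _chi2_result(stat, H - 1, table.n_informative, "mhet")


def one_vs_rest_counts(table: TransmissionTable, h: Haplotype) -> Tuple[int, int]:
    """Discordant counts for haplotype ``h`` against all others collapsed.

    A heterozygous parental genotype is discordant iff exactly one of its two
    haplotypes equals ``h``; in the heterozygous-only table that is every
    genotype transmitting (``T_h``) or nontransmitting (``U_h``) ``h``.
    """
    return table.t(h), table.u(h)


def tdt_max(table: TransmissionTable) -> TestResult:
    """Max one-vs-rest TDT (plain form).

    The maximum over haplotypes of the one-vs-rest biallelic TDT.  The plain
    statistic is not chi-square under the null for more than one marker, so
    the reported p-value is the Bonferroni bound min(1, H * tail) and is
    flagged as a bound.
    """
    H = table.n_distinct
    if H < 2:
        return TestResult(0.0, 1, 1.0, table.n_informative, "max", flags=(UNTESTABLE,))
    best_stat = 0.0
    best_h: Optional[Haplotype] = None
    for h in table.haplotypes:  # sorted: deterministic argmax tie-break
        b, c = one_vs_rest_counts(table, h)
        if b + c == 0:
            continue
        stat = (b - c) ** 2 / (b + c)
        if best_h is None or stat > best_stat:
            best_stat, best_h = stat, h
    p = min(1.0, H * float(chi2.sf(best_stat, 1)))
    flags: Tuple[str, ...] = (BONFERRONI_BOUND,)
    if table.n_informative == 0:
        return TestResult(0.0, 1, 1.0, 0, "max", flags=(NO_INFORMATIVE,))
    return TestResult(best_stat, 1, p, table.n_informative, "max", flags=flags)


def argmax_haplotype(table: TransmissionTable) -> Optional[Haplotype]:
    """Haplotype with the largest one-vs-rest TDT (lexicographic tie-break)."""
    best: Optional[Tuple[float, Haplotype]] = None
    for h in table.haplotypes:
        b, c = one_vs_rest_counts(table, h)
        if b + c == 0:
            continue
        stat = (b - c) ** 2 / (b + c)
        if best is None or stat > best[0]:
            best = (stat, h)
    return None if best is None else best[1]
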