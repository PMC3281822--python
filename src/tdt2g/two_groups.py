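"""The two-groups multimarker TDT (2G) and the generic holdout wrapper.

The 2G test collapses all window haplotypes into two groups learned from a
training subset of trios: a high-risk group g1 (haplotypes transmitted more
often than nontransmitted by heterozygous training parents) and a low-risk
group g2 (the converse); ties stay unassigned.  On the disjoint test subset a
parental genotype is informative iff it is heterozygous and its two
haplotypes fall in different groups — haplotypes unseen in training are
assigned to the group holding their most length-similar member, equal best
similarity leaving them unassigned.  The statistic is the McNemar chi-square
on the two informative cells,

    2G = (n_T - n_U)^2 / (n_T + n_U),

asymptotically chi-square with 1 df under no linkage regardless of window
width, because the grouping was learned on an independent half of the data.
The same split/fit/score scaffolding (``holdout_wrap``) builds honest 1-df or
fixed-df variants of the comparison tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Protocol, Tuple

import numpy as np
from scipy.stats import chi2

from .datasets import Haplotype, TrioDataset
from .haplotype_core import (
    ParentalTransmission,
    TransmissionTable,
    Window,
    count_transmissions,
    phase_dataset,
)
from .tdt_tests import (
    NO_INFORMATIVE,
    TestResult,
    argmax_haplotype,
    tdt_mhet,
)


@dataclass(frozen=True)
class GroupModel:
    """Two disjoint haplotype groups learned from a training subset."""

    g1: frozenset  # high-risk: transmitted more often than nontransmitted
    g2: frozenset  # low-risk: the converse
    window_width: int

    def __post_init__(self) -> None:
        if self.g1 & self.g2:
            raise ValueError("g1 and g2 must be disjoint")
        for h in self.g1 | self.g2:
            if len(h) != self.window_width:
                raise ValueError("group member length != window width")

    @property
    def empty(self) -> bool:
        return not self.g1 and not self.g2


@dataclass(frozen=True)
class TwoByTwoCounts:
    """The two informative cells of the collapsed group-by-group table."""

    n_t: int  # genotypes transmitting the g1-side haplotype
    n_u: int  # genotypes transmitting the g2-side haplotype

    def __post_init__(self) -> None:
        if self.n_t < 0 or self.n_u < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_used(self) -> int:
        return self.n_t + self.n_u


def holdout_split(
    trios: TrioDataset, fraction: float = 0.5, seed: int = 0
) -> Tuple[TrioDataset, TrioDataset]:
    """Randomly partition trios into training and test subsets.

    Families stay intact (the splitting unit is the trio, so the two parental
    genotypes of one family never straddle the split).  The training subset
    gets ``round(fraction * n)`` trios, rounding half up, so an odd count
    favors training.  Deterministic for a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(trios)
    if n < 2:
        raise ValueError("need at least 2 trios to split")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return trios.subset(perm[:n_train].tolist()), trios.subset(perm[n_train:].tolist())


def build_groups(training_table: TransmissionTable) -> GroupModel:
    """Assign each training haplotype to g1 (T > U), g2 (U > T) or neither."""
    g1, g2 = set(), set()
    width = 0
    for h in training_table.haplotypes:
        width = len(h)
        t, u = training_table.t(h), training_table.u(h)
        if t > u:
            g1.add(h)
        elif u > t:
            g2.add(h)
    return GroupModel(frozenset(g1), frozenset(g2), width)


def length_similarity(h1: Haplotype, h2: Haplotype) -> int:
    """Largest number of *consecutive* markers with matching alleles."""
    if len(h1) != len(h2):
        raise ValueError("haplotypes must have equal length")
    best = run = 0
    for a, b in zip(h1, h2):
        if a == b:
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


def assign_group(h: Haplotype, model: GroupModel) -> Optional[str]:
    """Place a test haplotype into "g1" or "g2", or ``None`` if unassignable.

    Members keep their own group; anything else goes to the group holding the
    most length-similar haplotype.  Equal best similarity to both groups (or
    an empty model) leaves the haplotype unassigned.
    """
    if h in model.g1:
        return "g1"
    if h in model.g2:
        return "g2"
    s1 = max((length_similarity(h, m) for m in model.g1), default=-1)
    s2 = max((length_similarity(h, m) for m in model.g2), default=-1)
    if s1 > s2:
        return "g1"
    if s2 > s1:
        return "g2"
    return None


def two_group_counts(
    test_transmissions: Iterable[ParentalTransmission], model: GroupModel
) -> TwoByTwoCounts:
    """Collapse test-subset transmissions onto the fitted groups.

    A parental genotype is used iff it is heterozygous and its two haplotypes
    land in different groups; genotypes with both haplotypes in one group (or
    any side unassigned) are treated as homozygous and skipped.
    """
    cache: Dict[Haplotype, Optional[str]] = {}

    def group_of(h: Haplotype) -> Optional[str]:
        if h not in cache:
            cache[h] = assign_group(h, model)
        return cache[h]

    n_t = n_u = 0
    for tx in test_transmissions:
        if not tx.heterozygous:
            continue
        gt = group_of(tx.transmitted)
        gu = group_of(tx.nontransmitted)
        if gt is None or gu is None or gt == gu:
            continue
        if gt == "g1":
            n_t += 1
        else:
            n_u += 1
    return TwoByTwoCounts(n_t, n_u)


def statistic_2g(counts: TwoByTwoCounts, test_name: str = "2g") -> TestResult:
    """McNemar chi-square (1 df) on the collapsed two-by-two counts."""
    n = counts.n_used
    if n == 0:
        return TestResult(0.0, 1, 1.0, 0, test_name, flags=(NO_INFORMATIVE,))
    stat = (counts.n_t - counts.n_u) ** 2 / n
    return TestResult(stat, 1, float(chi2.sf(stat, 1)), n, test_name)


# ---------------------------------------------------------------------------
# Generic holdout scaffolding


class BaseTest(Protocol):
    """A statistic that can be fit on training transmissions and scored on
    independent test transmissions."""

    name: str

    def fit(self, training_table: TransmissionTable) -> object: ...

    def score(
        self, test_transmissions: List[ParentalTransmission], model: object
    ) -> TestResult: ...


class TwoGroupsTest:
    """The 2G statistic as a fit/score pair."""

    name = "2g"

    def fit(self, training_table: TransmissionTable) -> GroupModel:
        return build_groups(training_table)

    def score(
        self, test_transmissions: List[ParentalTransmission], model: GroupModel
    ) -> TestResult:
        return statistic_2g(two_group_counts(test_transmissions, model), self.name)


class MaxTest:
    """Holdout max one-vs-rest TDT: the haplotype with the largest one-vs-rest
    statistic is selected on training, then tested one-vs-rest on the test
    subset as an exact 1-df McNemar test.  Unseen test haplotypes are mapped
    by length similarity (the selected haplotype forms g1, all other training
    haplotypes g2)."""

    name = "max"

    def fit(self, training_table: TransmissionTable) -> GroupModel:
        best = argmax_haplotype(training_table)
        if best is None:
            return GroupModel(frozenset(), frozenset(), 0)
        rest = frozenset(h for h in training_table.haplotypes if h != best)
        return GroupModel(frozenset([best]), rest, len(best))

    def score(
        self, test_transmissions: List[ParentalTransmission], model: GroupModel
    ) -> TestResult:
        return statistic_2g(two_group_counts(test_transmissions, model), self.name)


class MhetTest:
    """Holdout mhet: the haplotype set H is fixed on training; test haplotypes
    are mapped to their most length-similar training haplotype (ties skip the
    genotype) and the (H-1)/H-scaled statistic is computed with df = H - 1."""

    name = "mhet"

    def fit(self, training_table: TransmissionTable) -> Tuple[Haplotype, ...]:
        return tuple(training_table.haplotypes)

    def score(
        self,
        test_transmissions: List[ParentalTransmission],
        model: Tuple[Haplotype, ...],
    ) -> TestResult:
        reference = model
        if len(reference) < 2:
            return TestResult(0.0, 1, 1.0, 0, self.name, flags=("untestable",))
        cache: Dict[Haplotype, Optional[Haplotype]] = {}

        def map_to_reference(h: Haplotype) -> Optional[Haplotype]:
            if h in cache:
                return cache[h]
            if h in reference:
                cache[h] = h
                return h
            sims = [(length_similarity(h, r), r) for r in reference]
            best = max(s for s, _ in sims)
            hits = [r for s, r in sims if s == best]
            cache[h] = hits[0] if len(hits) == 1 else None
            return cache[h]

        mapped: List[ParentalTransmission] = []
        for tx in test_transmissions:
            if not tx.heterozygous:
                continue
            t = map_to_reference(tx.transmitted)
            u = map_to_reference(tx.nontransmitted)
            if t is None or u is None or t == u:
                continue
            mapped.append(ParentalTransmission(t, u, tx.family_id, tx.parent_role))
        table = count_transmissions(mapped)
        result = tdt_mhet(table, df=len(reference) - 1)
        return TestResult(
            result.statistic, result.df, result.p_value, result.n_informative,
            self.name, flags=result.flags,
        )


def cross_sample_test(
    base: BaseTest,
    training: TrioDataset,
    test: TrioDataset,
    window: Window,
) -> TestResult:
    """Fit ``base`` on one dataset and score it on another.

    With ``training is test`` this is the plain (same-data) variant of the
    statistic; with independent datasets it is the cross-sample protocol used
    for reproducibility studies.
    """
    train_txs, _ = phase_dataset(training, window)
    model = base.fit(count_transmissions(train_txs))
    test_txs, _ = phase_dataset(test, window)
    return base.score(test_txs, model).with_context(window=window)


def holdout_wrap(
    base: BaseTest,
    trios: TrioDataset,
    window: Window,
    fraction: float = 0.5,
    seed: int = 0,
) -> TestResult:
    """Split trios, fit ``base`` on the training half, score on the test half."""
    training, test = holdout_split(trios, fraction, seed)
    return cross_sample_test(base, training, test, window).with_context(seed=seed)


def test_2g(
    trios: TrioDataset,
    window: Optional[Window] = None,
    fraction: float = 0.5,
    seed: int = 0,
) -> TestResult:
    """The full holdout 2G pipeline on one window (defaults to the whole panel)."""
    if window is None:
        window = (0, trios.n_markers)
    return holdout_wrap(TwoGroupsTest(), trios, window, fraction, seed)
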