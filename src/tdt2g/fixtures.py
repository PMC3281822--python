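"""Deterministic fixtures: the two-marker worked example and small random
null datasets for property tests.

The worked example is a pair of 84-trio datasets (168 parental genotypes
each) over two biallelic markers with alleles A/a and B/b, whose
per-configuration transmitted/nontransmitted counts realize the published
training and test columns exactly.  Running the two-groups pipeline on the
pair with this fixed split reproduces the textbook numbers: training counts
T(AB)=40 vs U(AB)=56, groups g1 = {Ab, aB} and g2 = {AB} with ab unassigned
at fit time, similarity assignment of ab to g1 at test time, and the
collapsed test counts n_T = 51, n_U = 34 giving statistic (51-34)^2/85 = 3.4.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .datasets import Haplotype, TrioDataset, trio_from_phases
from .simulate import _phases_to_trios

AB: Haplotype = ("A", "B")
Ab: Haplotype = ("A", "b")
aB: Haplotype = ("a", "B")
ab: Haplotype = ("a", "b")

#: (transmitted, nontransmitted, training count, test count) per genotype
#: configuration; 16 rows = all ordered haplotype pairs of length 2.
WORKED_EXAMPLE_CONFIGS: Tuple[Tuple[Haplotype, Haplotype, int, int], ...] = (
    (AB, AB, 25, 30),
    (AB, Ab, 30, 24),
    (AB, aB, 3, 5),
    (AB, ab, 7, 5),
    (Ab, AB, 37, 31),
    (Ab, Ab, 21, 21),
    (Ab, aB, 6, 7),
    (Ab, ab, 5, 4),
    (aB, AB, 8, 9),
    (aB, Ab, 6, 8),
    (aB, aB, 2, 2),
    (aB, ab, 3, 3),
    (ab, AB, 11, 11),
    (ab, Ab, 3, 4),
    (ab, aB, 1, 2),
    (ab, ab, 0, 2),
)


def _materialize(column: int, prefix: str) -> TrioDataset:
    records = []
    for t, u, train, test in WORKED_EXAMPLE_CONFIGS:
        records.extend([(t, u)] * (train if column == 0 else test))
    assert len(records) % 2 == 0
    trios = []
    for j in range(0, len(records), 2):
        father, mother = records[j], records[j + 1]
        trios.append(trio_from_phases(f"{prefix}{j // 2}", father, mother))
    return TrioDataset(trios, 2)


def worked_example_dataset() -> Tuple[TrioDataset, TrioDataset]:
    """The printed training/test halves as phased 84-trio datasets.

    The split is fixed by construction (the random splitter is bypassed), so
    every downstream number is exact, not stochastic.  Bit-reproducible: the
    168 parental records of each half are paired into trios in configuration
    order.
    """
    return _materialize(0, "train"), _materialize(1, "test")


def random_trios(n: int, l: int, maf: float = 0.5, seed: int = 0) -> TrioDataset:
    """Null trios with no disease ascertainment, for calibration/property tests.

    Founder haplotypes have independent Bernoulli(maf) alleles at every
    marker; each parent transmits one of its two haplotypes uniformly at
    random.  Phased, Mendelian-consistent by construction, deterministic for
    a fixed seed.
    """
    if n < 1 or l < 1:
        raise ValueError("need n >= 1 and l >= 1")
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    rng = np.random.default_rng(seed)
    hap = rng.random((n, 2, 2, l)) < maf
    choice = rng.integers(0, 2, (n, 2))
    src = np.repeat(choice[..., None], l, axis=-1)
    t = np.take_along_axis(hap, src[:, :, None, :], axis=2).squeeze(2)
    u = np.take_along_axis(hap, (1 - src)[:, :, None, :], axis=2).squeeze(2)
    return TrioDataset(_phases_to_trios(t, u), l)
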