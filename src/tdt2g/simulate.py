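"""Trio simulators: stratified/admixed null populations, disease-linked trios
drawn from a coalescent haplotype pool, missing-data injection, and paired
draws for reproducibility studies.

All simulators ascertain on an affected child by rejection sampling: a
candidate trio is kept with probability proportional to the penetrance of the
child's disease-locus genotype (relative risks, baseline genotype weight 1).
Generated datasets are phased (the true transmitted/nontransmitted haplotype
pair of each parent is stored), Mendelian-consistent by construction, and the
disease locus itself is never part of the marker window.

Geometry conventions: the disease susceptibility locus sits at one extreme of
the low-recombination marker block; ``theta`` is the recombination fraction
between the block and the disease locus (0.5 = no linkage) and ``rho`` the
per-interval recombination fraction inside the block (default 1e-8, the
low-recombination-block estimate for an exponentially grown population).  For
two-locus models the second locus is unlinked to the block (theta = 0.5 by
construction: its alleles are drawn and transmitted independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .datasets import MISSING, Trio, TrioDataset, trio_from_phases
from .io_formats import HaplotypePool

_TOKENS = np.array(["1", "2"])  # allele 0 (major/ancestral) -> "1", 1 -> "2"

ONE_LOCUS_KINDS = ("additive", "dominant", "recessive")
TWO_LOCUS_KINDS = (
    "additive", "dom-and-dom", "rec-or-rec", "dom-or-dom", "threshold", "modified",
)


@dataclass(frozen=True)
class DiseaseModel:
    """Penetrance model for one or two biallelic disease loci.

    ``rr`` is the genotype relative risk f(DD)/f(dd) (and f(DDBB)/f(ddbb) for
    two loci).  Default per-genotype weights, indexed by disease-allele count:

    * one locus — dominant {0:1, 1:RR, 2:RR}; recessive {0:1, 1:1, 2:RR};
      additive {0:1, 1:(1+RR)/2, 2:RR}.
    * two loci — built from per-locus dominant (count >= 1) / recessive
      (count == 2) indicators: dom-and-dom / dom-or-dom / rec-or-rec apply RR
      when the conjunction/disjunction holds; threshold applies RR when the
      total disease-allele count is >= 2; additive is linear in the total
      count; "modified" is a documented placeholder (multiplicative per-locus
      dominant, RR^2 when both loci carry a disease allele).

    Any model can be overridden with an explicit ``penetrance_table`` (length
    3, or 3x3 for two loci) so exact published penetrances can be plugged in.
    ``baseline`` is the absolute penetrance of the weight-1 genotype; the
    ascertainment scheme only uses relative weights.
    """

    kind: str
    rr: float = 2.0
    n_loci: int = 1
    baseline: float = 0.05
    penetrance_table: Optional[Tuple] = None

    def __post_init__(self) -> None:
        valid = ONE_LOCUS_KINDS if self.n_loci == 1 else TWO_LOCUS_KINDS
        if self.n_loci not in (1, 2):
            raise ValueError("n_loci must be 1 or 2")
        if self.kind not in valid:
            raise ValueError(f"unknown {self.n_loci}-locus model kind {self.kind!r}")
        if self.rr < 1:
            raise ValueError("rr must be >= 1")

    def weights(self) -> np.ndarray:
        """Relative risk per disease genotype; shape (3,) or (3, 3)."""
        if self.penetrance_table is not None:
            w = np.asarray(self.penetrance_table, dtype=float)
            expected = (3,) if self.n_loci == 1 else (3, 3)
            if w.shape != expected:
                raise ValueError(f"penetrance_table must have shape {expected}")
            if w.max() <= 0:
                raise ValueError("penetrance_table has no positive entry")
            return w
        rr = self.rr
        if self.n_loci == 1:
            return {
                "dominant": np.array([1.0, rr, rr]),
                "recessive": np.array([1.0, 1.0, rr]),
                "additive": np.array([1.0, (1.0 + rr) / 2.0, rr]),
            }[self.kind]
        g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        dom1, dom2 = g1 >= 1, g2 >= 1
        rec1, rec2 = g1 == 2, g2 == 2
        if self.kind == "additive":
            return 1.0 + (rr - 1.0) * (g1 + g2) / 4.0
        if self.kind == "dom-and-dom":
            return np.where(dom1 & dom2, rr, 1.0)
        if self.kind == "dom-or-dom":
            return np.where(dom1 | dom2, rr, 1.0)
        if self.kind == "rec-or-rec":
            return np.where(rec1 | rec2, rr, 1.0)
        if self.kind == "threshold":
            return np.where(g1 + g2 >= 2, rr, 1.0)
        # "modified": multiplicative per-locus dominant placeholder
        return np.where(dom1, rr, 1.0) * np.where(dom2, rr, 1.0)


def penetrance(
    disease_genotypes: Union[int, Tuple[int, ...]], model: DiseaseModel
) -> float:
    """Relative risk weight of a child's disease genotype (allele counts)."""
    w = model.weights()
    if model.n_loci == 1:
        g = disease_genotypes if isinstance(disease_genotypes, int) else disease_genotypes[0]
        return float(w[g])
    g1, g2 = disease_genotypes  # type: ignore[misc]
    return float(w[g1, g2])


@dataclass
class StratificationConfig:
    """Two-subpopulation admixture design for the null (theta = 0.5) study.

    ``pp`` of the families come from subpopulation 1 (marker MAFs ``maf1``,
    disease-allele frequency ``p_d[0]``), the rest from subpopulation 2
    (MAF ``q``, frequency ``p_d[1]``).  Founder haplotypes have independent
    alleles at every marker.
    """

    n_families: int = 500
    pp: float = 0.5
    maf1: float = 0.5
    q: float = 0.1
    p_d: Tuple[float, float] = (0.05, 0.25)
    theta: float = 0.5
    l: int = 1
    rho: float = 1e-8
    model: DiseaseModel = field(default_factory=lambda: DiseaseModel("dominant", 2.0))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("pp", self.pp), ("maf1", self.maf1), ("q", self.q),
                        ("p_d1", self.p_d[0]), ("p_d2", self.p_d[1])):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must be in [0, 0.5]")


@dataclass
class PoolSimConfig:
    """Disease-linked trios with founder haplotypes drawn from a pool.

    The disease site is the pool site with derived-allele frequency inside
    ``disease_maf_range`` nearest to the right extreme of the block; the
    window is the ``l`` sites immediately upstream of it.  Transmitted
    haplotypes recombine with the partner haplotype at ``rho_within`` per
    marker interval and decouple from the disease-site allele with
    probability ``theta``.  Two-locus models draw the (unlinked) second-locus
    alleles at frequency ``second_locus_maf``.
    """

    pool: HaplotypePool
    n_families: int = 250
    l: int = 8
    disease_maf_range: Tuple[float, float] = (0.1, 0.5)
    theta: float = 0.0
    rho_within: float = 1e-8
    second_locus_maf: float = 0.25
    model: DiseaseModel = field(default_factory=lambda: DiseaseModel("dominant", 2.5))
    seed: int = 0


def _transmit(
    hap: np.ndarray, d: np.ndarray, theta: float, rho: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized gamete formation for a batch of parents.

    ``hap``: (k, 2 parents, 2 haplotypes, l markers) alleles; ``d``:
    (k, 2, 2) disease-site alleles paired with the haplotypes.  Returns the
    transmitted and nontransmitted marker haplotypes and the transmitted
    disease allele.  The disease locus adjoins the window end, so its linkage
    anchor is the gamete's source haplotype at the last marker.
    """
    k, _, _, l = hap.shape
    choice = rng.integers(0, 2, (k, 2))
    if rho > 0.0 and l > 1:
        crossover = rng.random((k, 2, l - 1)) < rho
        flips = np.cumsum(crossover, axis=-1) % 2
        src = np.concatenate([choice[..., None], choice[..., None] ^ flips], axis=-1)
    else:
        src = np.repeat(choice[..., None], l, axis=-1)
    t = np.take_along_axis(hap, src[:, :, None, :], axis=2).squeeze(2)
    u = np.take_along_axis(hap, (1 - src)[:, :, None, :], axis=2).squeeze(2)
    anchor = src[..., -1]
    decouple = rng.random((k, 2)) < theta
    dsrc = anchor ^ decouple
    d_trans = np.take_along_axis(d, dsrc[..., None], axis=2).squeeze(2)
    return t, u, d_trans


def _ascertained_batches(
    n: int,
    rng: np.random.Generator,
    draw: Callable[[int], Tuple[np.ndarray, np.ndarray, np.ndarray]],
    weights: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rejection-sample ``n`` affected-child trios.

    ``draw(k)`` produces one attempt for ``k`` candidate families and returns
    (t, u, per-family penetrance weight); accepted rows are accumulated until
    ``n`` trios exist.  Returns stacked (t, u) arrays of shape (n, 2, l).
    """
    wmax = float(weights.max())
    if wmax <= 0:
        raise ValueError("all penetrance weights are zero")
    t_rows: List[np.ndarray] = []
    u_rows: List[np.ndarray] = []
    remaining = n
    while remaining > 0:
        k = max(remaining * 2, 16)
        t, u, w = draw(k)
        accept = rng.random(k) * wmax < w
        idx = np.flatnonzero(accept)[:remaining]
        t_rows.append(t[idx])
        u_rows.append(u[idx])
        remaining -= len(idx)
    return np.concatenate(t_rows), np.concatenate(u_rows)


def _phases_to_trios(
    t: np.ndarray, u: np.ndarray, subpop: Optional[np.ndarray] = None,
    prefix: str = "fam",
) -> List[Trio]:
    """Convert 0/1 allele arrays (n, 2, l) into phased trios with tokens."""
    t_tok = _TOKENS[t.astype(int)].tolist()
    u_tok = _TOKENS[u.astype(int)].tolist()
    trios = []
    for j in range(len(t_tok)):
        trios.append(
            trio_from_phases(
                f"{prefix}{j}",
                (tuple(t_tok[j][0]), tuple(u_tok[j][0])),
                (tuple(t_tok[j][1]), tuple(u_tok[j][1])),
                subpop=None if subpop is None else int(subpop[j]),
            )
        )
    return trios


def simulate_stratified_null(cfg: StratificationConfig) -> TrioDataset:
    """Affected-child trios from an admixed pair of subpopulations.

    Marker founder alleles are independent Bernoulli draws at the
    subpopulation's MAF; the disease locus is linked to the window only
    through ``theta`` (0.5 in the null design, i.e. not at all).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_families
    n1 = int(round(cfg.pp * n))
    weights = cfg.model.weights()
    if cfg.model.n_loci != 1:
        raise ValueError("stratified design uses a one-locus model")

    def simulate_subpop(m: int, maf: float, pd: float) -> Tuple[np.ndarray, np.ndarray]:
        def draw(k: int):
            hap = rng.random((k, 2, 2, cfg.l)) < maf
            d = rng.random((k, 2, 2)) < pd
            t, u, d_trans = _transmit(hap, d, cfg.theta, cfg.rho, rng)
            return t, u, weights[d_trans.sum(axis=1)]

        return _ascertained_batches(m, rng, draw, weights)

    trios: List[Trio] = []
    for sub, m, maf, pd in (
        (0, n1, cfg.maf1, cfg.p_d[0]),
        (1, n - n1, cfg.q, cfg.p_d[1]),
    ):
        if m == 0:
            continue
        t, u = simulate_subpop(m, maf, pd)
        trios.extend(
            _phases_to_trios(t, u, subpop=np.full(m, sub), prefix=f"s{sub}f")
        )
    ds = TrioDataset(trios, cfg.l)
    ds.meta["subpop_counts"] = (n1, n - n1)
    return ds


def choose_disease_site(
    pool: HaplotypePool, maf_range: Tuple[float, float], l: int
) -> Tuple[int, List[int]]:
    """Pick the disease site (rightmost pool site with derived-allele
    frequency in range and >= l sites to its left) and the window's marker
    column indices."""
    P = np.asarray(pool.haplotypes)
    if P.size == 0:
        raise ValueError("empty haplotype pool")
    freq = P.mean(axis=0)
    lo, hi = maf_range
    candidates = [
        i for i in range(P.shape[1]) if lo <= freq[i] <= hi and i >= l
    ]
    if not candidates:
        raise ValueError(
            f"no pool site with derived-allele frequency in [{lo}, {hi}] "
            f"and {l} markers upstream"
        )
    d_site = candidates[-1]
    return d_site, list(range(d_site - l, d_site))


def simulate_disease_trios(cfg: PoolSimConfig) -> TrioDataset:
    """Affected-child trios whose founder haplotypes come from a pool."""
    rng = np.random.default_rng(cfg.seed)
    P = np.asarray(cfg.pool.haplotypes)
    d_site, marker_idx = choose_disease_site(cfg.pool, cfg.disease_maf_range, cfg.l)
    weights = cfg.model.weights()

    def draw(k: int):
        idx = rng.integers(0, P.shape[0], (k, 2, 2))
        drawn = P[idx]
        hap = drawn[:, :, :, marker_idx]
        d = drawn[:, :, :, d_site]
        t, u, d_trans = _transmit(hap, d, cfg.theta, cfg.rho_within, rng)
        g1 = d_trans.sum(axis=1)
        if cfg.model.n_loci == 1:
            return t, u, weights[g1]
        d2 = rng.random((k, 2, 2)) < cfg.second_locus_maf
        dsrc2 = rng.integers(0, 2, (k, 2))
        d2_trans = np.take_along_axis(d2, dsrc2[..., None], axis=2).squeeze(2)
        g2 = d2_trans.sum(axis=1)
        return t, u, weights[g1, g2]

    t, u = _ascertained_batches(cfg.n_families, rng, draw, weights)
    ds = TrioDataset(_phases_to_trios(t, u), cfg.l)
    ds.meta["disease_site"] = d_site
    ds.meta["marker_columns"] = marker_idx
    return ds


def sample_affected_trio(cfg: PoolSimConfig) -> Trio:
    """Draw a single ascertained trio from the pool design."""
    return simulate_disease_trios(replace(cfg, n_families=1))[0]


def inject_missing(
    ds: TrioDataset,
    proportion: float,
    seed: int = 0,
    _cells: Optional[np.ndarray] = None,
) -> TrioDataset:
    """Delete exactly floor(proportion * n_parents * n_markers) parent-marker
    genotype cells, uniformly without replacement.

    A touched parent loses its stored phase, so downstream analysis re-phases
    the whole trio from genotypes (and drops it for windows where the missing
    cell makes the parent unresolvable).  ``_cells`` lets a harness supply a
    pre-drawn uniform cell permutation whose prefix is used, so several
    proportions on the same dataset share nested missing sets (common random
    numbers); a prefix of a uniform permutation is itself a uniform draw
    without replacement.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must be in [0, 1)")
    l = ds.n_markers
    n_cells = 2 * len(ds) * l
    n_missing = int(np.floor(proportion * n_cells))
    if n_missing == 0:
        return TrioDataset(list(ds.trios), l, dict(ds.meta))
    if _cells is not None:
        cells = np.asarray(_cells)[:n_missing]
    else:
        cells = np.random.default_rng(seed).choice(
            n_cells, size=n_missing, replace=False
        )
    per_trio: dict = {}
    for c in cells.tolist():
        trio_idx, rem = divmod(c, 2 * l)
        parent, marker = divmod(rem, l)
        per_trio.setdefault(trio_idx, []).append((parent, marker))
    trios = list(ds.trios)
    for trio_idx, hits in per_trio.items():
        trio = trios[trio_idx]
        father = [list(p) for p in trio.father]
        mother = [list(p) for p in trio.mother]
        kw: dict = {}
        for parent, marker in hits:
            target = father if parent == 0 else mother
            target[marker] = [MISSING, MISSING]
            kw["father_phase" if parent == 0 else "mother_phase"] = None
        kw["father"] = tuple(tuple(p) for p in father)
        kw["mother"] = tuple(tuple(p) for p in mother)
        trios[trio_idx] = replace(trio, **kw)
    out = TrioDataset(trios, l, dict(ds.meta))
    out.meta["n_missing_cells"] = n_missing
    return out


def reproducibility_pair(
    population_sampler: Callable[[int], TrioDataset], seed: int = 0
) -> Tuple[TrioDataset, TrioDataset]:
    """Two independent same-size draws from one population sampler.

    The sampler receives two distinct seeds from disjoint spawned streams;
    identical seeds for the pair are asserted away.
    """
    streams = np.random.SeedSequence(seed).spawn(2)
    sa, sb = (int(s.generate_state(1)[0] % 2**31) for s in streams)
    if sa == sb:  # vanishingly unlikely; keep the streams disjoint regardless
        sb = (sb + 1) % 2**31
    return population_sampler(sa), population_sampler(sb)


def coalescent_pool(
    n_haplotypes: int = 200,
    sequence_length: float = 200_000.0,
    population_size: float = 10_000.0,
    mutation_rate: float = 1e-8,
    recombination_rate: float = 1e-8,
    maf_min: float = 0.05,
    thin: int = 6,
    seed: int = 1,
) -> HaplotypePool:
    """Generate a haplotype pool under the standard coalescent (msprime).

    The per-bp recombination rate defaults to the 1e-8 low-recombination
    estimate.  Two ascertainment steps emulate a genotyping-array marker
    panel: sites with minor-allele frequency below ``maf_min`` are discarded
    (arrays target common variants), then only every ``thin``-th surviving
    site is kept, matching array SNP spacing (sequence data are several-fold
    denser than array panels; set ``thin=1`` to keep every common site).
    """
    import msprime

    rs = max(1, seed % (2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_haplotypes // 2,
        ploidy=2,
        sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        population_size=population_size,
        random_seed=rs,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mutation_rate,
        random_seed=rs + 1,
        model=msprime.BinaryMutationModel(),
    )
    G = mts.genotype_matrix()  # (sites, haplotypes)
    positions = np.array([s.position / sequence_length for s in mts.sites()])
    freq = G.mean(axis=1)
    keep = np.minimum(freq, 1.0 - freq) >= maf_min
    G = G[keep]
    positions = positions[keep]
    if thin > 1:
        G = G[::thin]
        positions = positions[::thin]
    haps = [tuple(int(a) for a in col) for col in G.T.tolist()]
    return HaplotypePool(haps, tuple(positions.tolist()), source="msprime coalescent")
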