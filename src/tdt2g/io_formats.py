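"""File formats: LINKAGE PED/MAP trio genotypes, ms/msHOT haplotype pools,
and the tab-separated results table.

PED dialect: whitespace-separated pre-makeped rows
``fam id father mother sex phenotype a1 b1 a2 b2 ...`` with ``0`` as the
missing allele and as the "no parent" pointer.  Only complete trios (both
parents present in the file) are kept; a child allele configuration that is
Mendelian-impossible at a marker is downgraded to missing for that family
(the rest of the window survives) and logged.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, List, Optional, Sequence, Tuple

from .datasets import MISSING, Genotype, Trio, TrioDataset
from .haplotype_core import _marker_candidates
from .tdt_tests import TestResult


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered SNP panel: ids, physical positions and chromosome label."""

    marker_ids: Tuple[str, ...]
    positions: Tuple[int, ...]
    chromosome: str = "0"

    def __post_init__(self) -> None:
        if len(self.marker_ids) < 1:
            raise ValueError("panel needs at least one marker")
        if len(self.marker_ids) != len(self.positions):
            raise ValueError("ids and positions differ in length")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class HaplotypePool:
    """Phased binary haplotypes (0/1 alleles) drawn from one population."""

    haplotypes: List[Tuple[int, ...]]
    site_positions: Tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        n_sites = len(self.site_positions)
        for h in self.haplotypes:
            if len(h) != n_sites:
                raise ValueError("haplotype length != number of sites")
            if any(a not in (0, 1) for a in h):
                raise ValueError("alleles must be 0/1")

    @property
    def empty(self) -> bool:
        return len(self.site_positions) == 0

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


class PedFormatError(ValueError):
    """Malformed PED/MAP content; message carries the 1-based line number."""


def read_map(stream: IO[str]) -> MarkerPanel:
    chroms, ids, positions = [], [], []
    for lineno, line in enumerate(stream, 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise PedFormatError(f"MAP line {lineno}: expected 4 fields, got {len(fields)}")
        chroms.append(fields[0])
        ids.append(fields[1])
        try:
            positions.append(int(fields[3]))
        except ValueError as exc:
            raise PedFormatError(f"MAP line {lineno}: bad position {fields[3]!r}") from exc
    if not ids:
        raise PedFormatError("MAP file is empty")
    return MarkerPanel(tuple(ids), tuple(positions), chroms[0])


def _mendelian_clean(
    father: List[List[str]], mother: List[List[str]], child: List[List[str]]
) -> int:
    """Downgrade Mendelian-impossible child markers to missing; return count."""
    n_bad = 0
    for i, (f, m, c) in enumerate(zip(father, mother, child)):
        if MISSING in c:
            continue
        if not _marker_candidates(tuple(f), tuple(m), tuple(c)):
            child[i] = [MISSING, MISSING]
            n_bad += 1
    return n_bad


def read_ped_map(
    ped_stream: IO[str], map_stream: IO[str]
) -> Tuple[TrioDataset, MarkerPanel]:
    """Parse a PED/MAP pair into complete trios aligned to MAP marker order.

    The returned dataset's ``meta`` reports families excluded for missing
    parents and per-family Mendelian-inconsistent markers set missing.
    """
    panel = read_map(map_stream)
    l = len(panel)
    individuals = {}  # (fam, iid) -> (father_id, mother_id, genotype rows)
    order = []
    for lineno, line in enumerate(ped_stream, 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * l:
            raise PedFormatError(
                f"PED line {lineno}: expected {6 + 2 * l} fields for {l} markers, "
                f"got {len(fields)}"
            )
        fam, iid, pat, mat = fields[:4]
        alleles = fields[6:]
        gt = [[alleles[2 * i], alleles[2 * i + 1]] for i in range(l)]
        individuals[(fam, iid)] = (pat, mat, gt)
        order.append((fam, iid))

    trios = []
    excluded = 0
    mendel_flagged = 0
    for fam, iid in order:
        pat, mat, child_gt = individuals[(fam, iid)]
        if pat == "0" or mat == "0":
            continue  # a founder, not a child
        father_rec = individuals.get((fam, pat))
        mother_rec = individuals.get((fam, mat))
        if father_rec is None or mother_rec is None:
            excluded += 1
            continue
        father_gt = [list(p) for p in father_rec[2]]
        mother_gt = [list(p) for p in mother_rec[2]]
        child = [list(p) for p in child_gt]
        mendel_flagged += _mendelian_clean(father_gt, mother_gt, child)

        def freeze(rows: List[List[str]]) -> Genotype:
            return tuple(tuple(sorted(pair)) for pair in rows)  # type: ignore[return-value]

        trios.append(
            Trio(fam, freeze(father_gt), freeze(mother_gt), freeze(child))
        )
    ds = TrioDataset(trios, l)
    ds.meta["excluded_families"] = excluded
    ds.meta["mendelian_flagged_markers"] = mendel_flagged
    return ds, panel


def write_ped_map(
    ds: TrioDataset,
    panel: MarkerPanel,
    ped_stream: IO[str],
    map_stream: IO[str],
) -> None:
    """Write trios as pre-makeped PED rows (father, mother, affected child)."""
    if len(panel) != ds.n_markers:
        raise ValueError("panel size does not match dataset")
    for mid, pos in zip(panel.marker_ids, panel.positions):
        map_stream.write(f"{panel.chromosome}\t{mid}\t0\t{pos}\n")
    for i, trio in enumerate(ds):
        fam = trio.family_id or f"fam{i}"
        rows = [
            (f"{fam}_f", "0", "0", "1", "1", trio.father),
            (f"{fam}_m", "0", "0", "2", "1", trio.mother),
            (f"{fam}_c", f"{fam}_f", f"{fam}_m", "0", "2", trio.child),
        ]
        for iid, pat, mat, sex, pheno, gt in rows:
            alleles = " ".join(f"{a} {b}" for a, b in gt)
            ped_stream.write(f"{fam} {iid} {pat} {mat} {sex} {pheno} {alleles}\n")


class MsFormatError(ValueError):
    pass


def read_ms(stream: IO[str], replicate: int = 0) -> HaplotypePool:
    """Parse one replicate block of ms/msHOT output into a haplotype pool."""
    lines = [ln.rstrip("\n") for ln in stream]
    starts = [i for i, ln in enumerate(lines) if ln.startswith("//")]
    if not starts:
        raise MsFormatError("no replicate block ('//') found")
    if replicate >= len(starts):
        raise MsFormatError(f"replicate {replicate} requested, only {len(starts)} present")
    i = starts[replicate]
    end = starts[replicate + 1] if replicate + 1 < len(starts) else len(lines)
    block = [ln for ln in lines[i + 1 : end] if ln.strip()]
    if not block or not block[0].startswith("segsites:"):
        raise MsFormatError("expected 'segsites:' after '//'")
    segsites = int(block[0].split()[1])
    if segsites == 0:
        return HaplotypePool([], (), source="ms")
    if len(block) < 2 or not block[1].startswith("positions:"):
        raise MsFormatError("expected 'positions:' line")
    positions = tuple(float(x) for x in block[1].split()[1:])
    if len(positions) != segsites:
        raise MsFormatError("positions count != segsites")
    haps = []
    for row in block[2:]:
        if len(row) != segsites:
            raise MsFormatError(
                f"haplotype row length {len(row)} != segsites {segsites}"
            )
        haps.append(tuple(int(ch) for ch in row))
    return HaplotypePool(haps, positions, source="ms")


def write_ms(pool: HaplotypePool, stream: IO[str]) -> None:
    """Write a pool as a single ms replicate block."""
    stream.write("//\n")
    stream.write(f"segsites: {pool.n_sites}\n")
    if pool.empty:
        return
    stream.write("positions: " + " ".join(f"{p:.5f}" for p in pool.site_positions) + "\n")
    for h in pool.haplotypes:
        stream.write("".join(str(a) for a in h) + "\n")


RESULTS_HEADER = (
    "chrom\twindow_start_marker\twindow_end_marker\tn_informative\t"
    "statistic\tdf\tp_value\ttest_name\tseed"
)


def write_results(
    results: Sequence[TestResult],
    stream: IO[str],
    chrom: str = "0",
) -> None:
    """Tab-separated results, one row per window, ordered by window start.

    Window coordinates are written as 1-based inclusive marker indices
    (internal indexing is 0-based half-open).
    """
    stream.write(RESULTS_HEADER + "\n")
    for r in sorted(results, key=lambda r: (r.window or (0, 0))[0]):
        start, stop = r.window if r.window is not None else (0, 0)
        seed = "" if r.seed is None else str(r.seed)
        stream.write(
            f"{chrom}\t{start + 1}\t{stop}\t{r.n_informative}\t"
            f"{r.statistic:.2f}\t{r.df}\t{r.p_value:.4g}\t{r.test_name}\t{seed}\n"
        )
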