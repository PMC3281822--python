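"""Trio phase resolution and per-haplotype transmission counting.

Family-based phasing: for every marker in a window the allele a parent
transmitted to the child is deduced from the three genotypes alone.  The
transmitted gamete over the window is one parental haplotype, the remaining
alleles form the nontransmitted one.  A parent resolves only when the
transmitted allele is unique at *every* window marker and the parent has no
missing calls in the window; anything else (double-heterozygote ambiguity,
missing data, Mendelian impossibility) leaves the parent unresolved — no
phase is ever guessed.  Population-level phasing (E-M, sampling) is a
deliberate non-goal: unresolved parents are dropped from the window.

Transmission counts feed every statistic downstream: per distinct haplotype
``i``, ``T_i`` is the number of heterozygous parental genotypes transmitting
``i`` and ``U_i`` the number nontransmitting it.  Homozygous parents
(transmitted == nontransmitted) are uninformative and excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .datasets import MISSING, Genotype, GenotypePair, Haplotype, Trio, TrioDataset

Window = Tuple[int, int]  # 0-based half-open [start, stop)


@dataclass(frozen=True)
class ParentalTransmission:
    """One parent's (transmitted, nontransmitted) haplotype pair in a window."""

    transmitted: Haplotype
    nontransmitted: Haplotype
    family_id: str
    parent_role: str  # "father" | "mother"

    @property
    def heterozygous(self) -> bool:
        return self.transmitted != self.nontransmitted


@dataclass(frozen=True)
class PhaseResult:
    """Outcome of phasing one trio over a window.

    ``father``/``mother`` are ``None`` when that parent could not be resolved;
    ``reason`` holds the first failure encountered ("mendelian", "missing" or
    "ambiguous"), or ``None`` when both parents resolved.
    """

    father: Optional[ParentalTransmission]
    mother: Optional[ParentalTransmission]
    reason: Optional[str] = None

    @property
    def resolved(self) -> bool:
        return self.father is not None and self.mother is not None


def _marker_candidates(
    f: GenotypePair, m: GenotypePair, c: GenotypePair
) -> set:
    """All (father-transmitted, mother-transmitted) allele pairs consistent
    with one marker's three genotypes.  ``None`` stands in for a parent with a
    missing call (it can still constrain the spouse)."""
    f_known = MISSING not in f
    m_known = MISSING not in m
    c_known = MISSING not in c
    cands = set()
    for cf in (set(f) if f_known else {None}):
        for cm in (set(m) if m_known else {None}):
            if c_known:
                if cf is not None and cm is not None:
                    if sorted((cf, cm)) != sorted(c):
                        continue
                elif cf is not None and cf not in c:
                    continue
                elif cm is not None and cm not in c:
                    continue
            cands.add((cf, cm))
    return cands


def phase_trio(
    father: Genotype,
    mother: Genotype,
    child: Genotype,
    family_id: str = "fam",
) -> PhaseResult:
    """Resolve both parental transmissions over a (pre-sliced) window.

    Returns a :class:`PhaseResult`; a Mendelian impossibility at any marker
    unresolves the whole trio, other failures are per parent.
    """
    l = len(father)
    if not (len(mother) == len(child) == l):
        raise ValueError("genotypes differ in length")
    ft: List[Optional[str]] = []
    mt: List[Optional[str]] = []
    for i in range(l):
        cands = _marker_candidates(father[i], mother[i], child[i])
        if not cands:
            return PhaseResult(None, None, "mendelian")
        fs = {cf for cf, _ in cands}
        ms = {cm for _, cm in cands}
        ft.append(fs.pop() if len(fs) == 1 else None)
        mt.append(ms.pop() if len(ms) == 1 else None)

    def build(role: str, gt: Genotype, trans: List[Optional[str]]):
        if any(MISSING in pair for pair in gt):
            return None, "missing"
        if any(a is None for a in trans):
            return None, "ambiguous"
        nontrans = tuple(b if t == a else a for t, (a, b) in zip(trans, gt))
        tx = ParentalTransmission(tuple(trans), nontrans, family_id, role)  # type: ignore[arg-type]
        return tx, None

    f_tx, f_reason = build("father", father, ft)
    m_tx, m_reason = build("mother", mother, mt)
    return PhaseResult(f_tx, m_tx, f_reason or m_reason)


def phase_dataset(
    ds: TrioDataset, window: Window
) -> Tuple[List[ParentalTransmission], int]:
    """Collect both parental transmissions of every resolvable trio.

    Trios with stored (simulated) phase are sliced directly; all other trios
    are phased from their genotypes.  A trio contributes only when *both*
    parents resolve, so the returned list always holds ``2 * n_used`` records.
    Returns ``(transmissions, n_dropped_trios)``.
    """
    start, stop = window
    if not (0 <= start < stop <= ds.n_markers):
        raise ValueError(f"window {window} outside panel of {ds.n_markers} markers")
    txs: List[ParentalTransmission] = []
    dropped = 0
    for trio in ds:
        if trio.father_phase is not None and trio.mother_phase is not None:
            for role, phase in (("father", trio.father_phase), ("mother", trio.mother_phase)):
                txs.append(
                    ParentalTransmission(
                        phase[0][start:stop], phase[1][start:stop], trio.family_id, role
                    )
                )
        else:
            res = phase_trio(
                trio.father[start:stop],
                trio.mother[start:stop],
                trio.child[start:stop],
                trio.family_id,
            )
            if res.resolved:
                txs.extend([res.father, res.mother])  # type: ignore[list-item]
            else:
                dropped += 1
    return txs, dropped


class TransmissionTable:
    """Per-haplotype transmitted/nontransmitted counts from heterozygous parents.

    Invariant: sum of ``T`` = sum of ``U`` = ``n_informative`` (each informative
    parent adds exactly one transmitted and one nontransmitted haplotype).
    """

    def __init__(self) -> None:
        self._t: Counter = Counter()
        self._u: Counter = Counter()
        self.n_informative: int = 0

    def t(self, h: Haplotype) -> int:
        return self._t[h]

    def u(self, h: Haplotype) -> int:
        return self._u[h]

    @property
    def haplotypes(self) -> List[Haplotype]:
        return sorted(set(self._t) | set(self._u))

    @property
    def n_distinct(self) -> int:
        return len(set(self._t) | set(self._u))

    def as_dict(self) -> Dict[Haplotype, Tuple[int, int]]:
        return {h: (self._t[h], self._u[h]) for h in self.haplotypes}

    def __repr__(self) -> str:
        cells = ", ".join(
            f"{''.join(h)}:{self._t[h]}/{self._u[h]}" for h in self.haplotypes
        )
        return f"TransmissionTable({cells}; n={self.n_informative})"


def count_transmissions(
    transmissions: Iterable[ParentalTransmission],
) -> TransmissionTable:
    """Tally ``T_i``/``U_i`` over all heterozygous parental transmissions."""
    table = TransmissionTable()
    for tx in transmissions:
        if not tx.heterozygous:
            continue
        table._t[tx.transmitted] += 1
        table._u[tx.nontransmitted] += 1
        table.n_informative += 1
    return table
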