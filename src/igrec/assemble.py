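"""Single-k de Bruijn graph assembly of the extracted Ig read set.

A full transcriptome assembler is unnecessary for this problem: the input is
a small read set dominated by one clonally amplified Ig transcript at very
high coverage, plus a few minor clones. A single-k de Bruijn graph over
canonical k-mers, with an abundance floor, tip pruning and bubble collapse,
reconstructs such transcripts reliably.

Graph cleaning has three layers:

* an absolute k-mer count floor (``min_kmer_count``, default 2) absorbing
  singleton sequencing errors;
* a relative abundance floor -- k-mers below ``rel_abundance_floor`` times
  the 90th-percentile k-mer count are dropped. At clonal coverage in the
  thousands, individual sequencing errors recur two or three times and would
  otherwise pass the absolute floor and shatter the graph; the relative
  floor removes them while keeping minor clones two orders of magnitude
  below the dominant one;
* topological cleanup on the remaining graph: dead-end branches ("tips")
  shorter than 2k whose coverage is far below a sibling branch are pruned,
  and parallel paths ("bubbles") with sequence identity above
  ``bubble_identity`` collapse to the higher-coverage branch.

Contigs are the maximal unambiguous paths of the cleaned graph, each emitted
once in canonical orientation (lexicographically smaller of the sequence and
its reverse complement) and in deterministic order.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .align import revcomp
from .io import ReadPair


@dataclass(frozen=True)
class AssemblyConfig:
    k: int = 25
    min_kmer_count: int = 2
    min_contig_length: int = 200
    bubble_identity: float = 0.98
    rel_abundance_floor: float = 0.005
    tip_coverage_ratio: float = 0.25
    branch_thin_ratio: float = 0.2
    max_cleanup_rounds: int = 8

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 15:
            raise ValueError("k must be odd and >= 15")
        if self.min_contig_length < self.k:
            raise ValueError("min_contig_length must be >= k")


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    k_coverage: float
    n_reads_supporting: int


def _canon(km: str) -> str:
    r = revcomp(km)
    return km if km <= r else r


def _iter_seqs(reads: Iterable[ReadPair | tuple[str, str] | str]) -> list[str]:
    seqs: list[str] = []
    for r in reads:
        if isinstance(r, ReadPair):
            seqs.extend((r.seq1, r.seq2))
        elif isinstance(r, str):
            seqs.append(r)
        else:
            seqs.extend((r[0], r[1]))
    return [s.upper() for s in seqs]


def _count_kmers(seqs: Sequence[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            counts[_canon(km)] += 1
    return counts


class _Graph:
    """De Bruijn graph over an oriented k-mer set (each canonical k-mer is
    present in both orientations)."""

    def __init__(self, canon_kmers: set[str], counts: Counter, k: int) -> None:
        self.k = k
        self.counts = counts
        self.oriented: set[str] = set()
        for km in canon_kmers:
            self.oriented.add(km)
            self.oriented.add(revcomp(km))

    def remove_canon(self, kmers: Iterable[str]) -> None:
        for km in kmers:
            self.oriented.discard(km)
            self.oriented.discard(revcomp(km))

    def succs(self, km: str) -> list[str]:
        suffix = km[1:]
        return [suffix + b for b in "ACGT" if suffix + b in self.oriented]

    def preds(self, km: str) -> list[str]:
        prefix = km[:-1]
        return [b + prefix for b in "ACGT" if b + prefix in self.oriented]

    def coverage(self, km: str) -> int:
        return self.counts[_canon(km)]


@dataclass
class _Unitig:
    kmers: list[str]  # oriented path

    @property
    def first(self) -> str:
        return self.kmers[0]

    @property
    def last(self) -> str:
        return self.kmers[-1]

    @property
    def sequence(self) -> str:
        return self.kmers[0] + "".join(km[-1] for km in self.kmers[1:])

    def coverage(self, g: _Graph) -> float:
        return float(np.mean([g.coverage(km) for km in self.kmers]))

    def canon_kmers(self) -> set[str]:
        return {_canon(km) for km in self.kmers}


def _extract_unitigs(g: _Graph) -> list[_Unitig]:
    """Maximal non-branching paths; each unitig emitted once (its reverse
    complement is suppressed). Deterministic: starts visited in sorted
    order."""
    visited: set[str] = set()
    unitigs: list[_Unitig] = []

    def walk(start: str) -> _Unitig:
        chain = [start]
        in_chain = {start, revcomp(start)}
        cur = start
        while True:
            nxt = g.succs(cur)
            if len(nxt) != 1:
                break
            z = nxt[0]
            if len(g.preds(z)) != 1 or z in visited or z in in_chain:
                break
            chain.append(z)
            in_chain.add(z)
            in_chain.add(revcomp(z))
            cur = z
        return _Unitig(chain)

    def is_start(u: str) -> bool:
        p = g.preds(u)
        if len(p) != 1:
            return True
        return len(g.succs(p[0])) != 1

    for u in sorted(g.oriented):
        if u in visited or not is_start(u):
            continue
        uni = walk(u)
        rc_seq = revcomp(uni.sequence)
        for km in uni.kmers:
            visited.add(km)
            visited.add(revcomp(km))
        # keep canonical orientation representative only once
        if uni.sequence <= rc_seq:
            unitigs.append(uni)
        else:
            unitigs.append(_Unitig([revcomp(km) for km in reversed(uni.kmers)]))

    # isolated cycles
    for u in sorted(g.oriented):
        if u in visited:
            continue
        chain = [u]
        visited.add(u)
        visited.add(revcomp(u))
        cur = u
        while True:
            nxt = [z for z in g.succs(cur) if z not in visited]
            if not nxt:
                break
            cur = sorted(nxt)[0]
            chain.append(cur)
            visited.add(cur)
            visited.add(revcomp(cur))
        unitigs.append(_Unitig(chain))
    return unitigs


def _bubble_mergeable(a: str, b: str, bubble_identity: float) -> bool:
    """Parallel branches merge when their edit distance stays within the
    identity budget; at least one edit is always allowed so that a
    single-substitution bubble (branch length 2k-1) collapses for any k."""
    d = min(
        edlib.align(a, b, task="distance")["editDistance"],
        edlib.align(a, revcomp(b), task="distance")["editDistance"],
    )
    budget = max(1, int((1.0 - bubble_identity) * max(len(a), len(b))))
    return d <= budget


def _thin_branches(g: _Graph, ratio: float) -> set[str]:
    """At every fork, drop outgoing k-mers whose count is below ``ratio``
    times the best sibling's count (local error-edge thinning; overlapping
    error bubbles that defeat same-anchor bubble detection are removed at
    their entry points instead). Both fork directions are covered because
    every k-mer is present in both orientations."""
    removed: set[str] = set()
    for u in sorted(g.oriented):
        succ = g.succs(u)
        if len(succ) < 2:
            continue
        covs = {z: g.coverage(z) for z in succ}
        best = max(covs.values())
        for z, c in covs.items():
            if c < ratio * best:
                removed.add(_canon(z))
    return removed


def _cleanup_round(g: _Graph, cfg: AssemblyConfig) -> bool:
    """One round of branch thinning + tip pruning + bubble collapse;
    returns True if anything was removed."""
    thinned = _thin_branches(g, cfg.branch_thin_ratio)
    if thinned:
        g.remove_canon(thinned)
    unis = _extract_unitigs(g)
    by_first: dict[str, _Unitig] = {}
    for u in unis:
        by_first[u.first] = u
        by_first[revcomp(u.last)] = u

    removed: set[str] = set()

    def sibling_cov(junction_children: list[str], exclude: str, index: dict[str, _Unitig]) -> float:
        covs = [index[c].coverage(g) for c in junction_children if c != exclude and c in index]
        return max(covs, default=0.0)

    # --- tips ---
    for u in unis:
        if len(u.sequence) >= 2 * g.k:
            continue
        for first, last in ((u.first, u.last), (revcomp(u.last), revcomp(u.first))):
            dead_head = len(g.preds(first)) == 0
            dead_tail = len(g.succs(last)) == 0
            if not (dead_tail and not dead_head):
                continue
            # the head attaches to a junction: compare against siblings there
            anchors = g.preds(first)
            if len(anchors) != 1:
                continue
            best_sib = sibling_cov(g.succs(anchors[0]), first, by_first)
            if best_sib > 0 and u.coverage(g) < cfg.tip_coverage_ratio * best_sib:
                removed |= u.canon_kmers()
            break
    # --- bubbles ---
    groups: dict[tuple, list[_Unitig]] = {}
    for u in unis:
        if u.canon_kmers() & removed:
            continue
        key_f = (tuple(sorted(g.preds(u.first))), tuple(sorted(g.succs(u.last))))
        rc_first, rc_last = revcomp(u.last), revcomp(u.first)
        key_r = (tuple(sorted(g.preds(rc_first))), tuple(sorted(g.succs(rc_last))))
        key = min(key_f, key_r)
        if not key[0] or not key[1]:
            continue
        groups.setdefault(key, []).append(u)
    for key, members in groups.items():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda u: (-u.coverage(g), u.sequence))
        keeper = members[0]
        for other in members[1:]:
            if _bubble_mergeable(keeper.sequence, other.sequence, cfg.bubble_identity):
                removed |= other.canon_kmers()

    if removed:
        g.remove_canon(removed)
    return bool(removed) or bool(thinned)


def assemble(
    reads: Iterable[ReadPair | tuple[str, str] | str],
    cfg: AssemblyConfig = AssemblyConfig(),
) -> list[Contig]:
    """Assemble reads into transcript contigs.

    Accepts :class:`ReadPair` objects, (seq1, seq2) tuples or plain
    sequences. Returns contigs of length >= ``min_contig_length`` in
    canonical orientation, sorted by decreasing length then sequence.
    Empty input yields an empty list with a warning; input in which every
    read is shorter than k is an error.
    """
    seqs = _iter_seqs(reads)
    if not seqs:
        warnings.warn("no reads supplied to the assembler")
        return []
    if all(len(s) < cfg.k for s in seqs):
        raise ValueError(f"all reads shorter than k={cfg.k}")

    counts = _count_kmers(seqs, cfg.k)
    kept = {km for km, c in counts.items() if c >= cfg.min_kmer_count}
    if not kept:
        warnings.warn("no k-mer passed the abundance floor")
        return []
    floor = cfg.min_kmer_count
    if cfg.rel_abundance_floor > 0:
        # instance-weighted median k-mer count: robust against the large
        # number of *distinct* low-count error k-mers, since genuine k-mers
        # carry almost all of the count mass
        vals = sorted(counts[km] for km in kept)
        total = sum(vals)
        acc = 0
        wmedian = vals[-1]
        for v in vals:
            acc += v
            if acc * 2 >= total:
                wmedian = v
                break
        floor = max(floor, int(np.ceil(cfg.rel_abundance_floor * wmedian)))
        kept = {km for km in kept if counts[km] >= floor}
    if not kept:
        warnings.warn("no k-mer passed the abundance floor")
        return []

    g = _Graph(kept, counts, cfg.k)
    for _ in range(cfg.max_cleanup_rounds):
        if not _cleanup_round(g, cfg):
            break

    finals = []
    for u in _extract_unitigs(g):
        seq = u.sequence
        seq = min(seq, revcomp(seq))
        if len(seq) >= cfg.min_contig_length:
            finals.append((seq, u.coverage(g), u.canon_kmers()))
    finals.sort(key=lambda t: (-len(t[0]), t[0]))

    # read support: number of reads sharing >= 1 k-mer with the contig
    kmer_to_contig: dict[str, set[int]] = {}
    for idx, (_seq, _cov, kms) in enumerate(finals):
        for km in kms:
            kmer_to_contig.setdefault(km, set()).add(idx)
    support = [0] * len(finals)
    for s in seqs:
        hit: set[int] = set()
        for i in range(len(s) - cfg.k + 1):
            km = s[i : i + cfg.k]
            if "N" in km:
                continue
            hit |= kmer_to_contig.get(_canon(km), set())
        for idx in hit:
            support[idx] += 1

    return [
        Contig(id=f"contig_{i + 1}", sequence=seq, k_coverage=cov, n_reads_supporting=support[i])
        for i, (seq, cov, _k) in enumerate(finals)
    ]
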