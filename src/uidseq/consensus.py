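"""UID-family grouping, error-tolerant UID clustering and consensus calling.

Raw reads carrying a unique identifier (UID, also called a UMI) are grouped
by their mapping key (chromosome, 5' mapping coordinate, strand).  Within a
group, UIDs that differ only by sequencing or PCR errors are merged by the
*directional* adjacency rule: a high-count UID absorbs a Hamming-distance-1
neighbour ``b`` whenever ``count(a) >= 2 * count(b) - 1``.  Each resulting
UID family is collapsed into a single high-confidence consensus read by
per-position majority vote, provided the family holds at least
``min_family_size`` reads (default 3).  Consensus reads approximate the
original, pre-amplification DNA fragments and carry a strongly reduced
per-base error rate, which is what makes sub-percent allele fractions
accessible in cell-free DNA.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_VALID_UID_CHARS = frozenset("ACGTN")
_BASES = b"ACGT"


@dataclass(slots=True)
class TaggedRead:
    """A single UID-tagged, mapped read.

    ``pos`` is the 0-based 5' mapping coordinate: for a ``+`` strand read it
    is the leftmost reference coordinate, for a ``-`` strand read the
    rightmost.  ``sequence`` is always stored in reference orientation
    (leftmost base first), so the leftmost covered coordinate of a ``-``
    strand read is ``pos - len(sequence) + 1``.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    uid: str
    sequence: str

    @property
    def leftmost(self) -> int:
        if self.strand == "-":
            return self.pos - len(self.sequence) + 1
        return self.pos


@dataclass(slots=True)
class ConsensusRead:
    """Majority-vote collapse of one UID family (a high-confidence read)."""

    chrom: str
    pos: int          # 5' coordinate shared by the family
    strand: str
    uid: str          # canonical UID of the family
    sequence: str     # reference orientation; may contain N at tied positions
    family_size: int

    @property
    def leftmost(self) -> int:
        if self.strand == "-":
            return self.pos - len(self.sequence) + 1
        return self.pos


@dataclass(slots=True)
class UIDCluster:
    """One cluster of UID strings within a mapping-position group."""

    canonical: str            # highest-count UID in the cluster
    uids: tuple[str, ...]     # all member UID strings
    size: int                 # summed read count


@dataclass(slots=True)
class UIDFamily:
    """Reads sharing a mapping key and a UID cluster."""

    chrom: str
    pos: int
    strand: str
    uid: str                          # canonical UID
    member_read_ids: tuple[str, ...]
    size: int
    consensus: ConsensusRead | None = None


@dataclass(frozen=True)
class FamilyStats:
    """Read-weighted family-size composition of one sample.

    Band conventions: *small* families (1-2 reads) cannot be collapsed,
    *optimal* families (3-50) yield consensus reads efficiently, *large*
    families (>50) are redundant sequencing.  The three fractions are
    fractions of raw reads and sum to 1.
    """

    n_raw_reads: int
    n_families: int
    n_consensus: int
    fraction_small: float
    fraction_optimal: float
    fraction_large: float
    mean_family_size: float
    families_per_million_raw: float
    unique_per_raw: float


def group_by_position(
    reads: Sequence[TaggedRead],
) -> dict[tuple[str, int, str], dict[str, list[int]]]:
    """Partition reads by (chrom, 5' position, strand), then by exact UID.

    Returns a mapping  key -> {uid: [read indices]}.  Reads with malformed
    UIDs (characters outside ACGTN) are rejected with a logged warning and
    do not appear in any group.
    """
    groups: dict[tuple[str, int, str], dict[str, list[int]]] = defaultdict(
        lambda: defaultdict(list)
    )
    n_rejected = 0
    for i, read in enumerate(reads):
        if not set(read.uid) <= _VALID_UID_CHARS:
            n_rejected += 1
            logger.warning("rejecting read %s: malformed UID %r", read.read_id, read.uid)
            continue
        groups[(read.chrom, read.pos, read.strand)][read.uid].append(i)
    if n_rejected:
        logger.warning("%d reads rejected for malformed UIDs", n_rejected)
    return {k: dict(v) for k, v in groups.items()}


def _hamming1_neighbours(uids: Iterable[str]) -> dict[str, list[str]]:
    """Hamming-distance-1 adjacency via the positional wildcard index."""
    index: dict[tuple[int, str], list[str]] = defaultdict(list)
    uids = list(uids)
    for u in uids:
        for i in range(len(u)):
            index[(i, u[:i] + u[i + 1 :])].append(u)
    nbrs: dict[str, set[str]] = {u: set() for u in uids}
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for a in bucket:
            for b in bucket:
                if a != b:
                    nbrs[a].add(b)
    return {u: sorted(v) for u, v in nbrs.items()}


def cluster_uids_directional(uid_counts: Mapping[str, int]) -> list[UIDCluster]:
    """Cluster UIDs with the directional adjacency rule.

    A directed edge ``a -> b`` exists iff Hamming(a, b) == 1 and
    ``count(a) >= 2 * count(b) - 1``.  Nodes are visited in descending count
    (ties broken lexicographically); each unassigned node seeds a cluster
    that is expanded breadth-first along directed edges into unassigned
    nodes only.  The canonical UID is the seed, which is necessarily the
    highest-count member.
    """
    if not uid_counts:
        return []
    order = sorted(uid_counts, key=lambda u: (-uid_counts[u], u))
    nbrs = _hamming1_neighbours(uid_counts)
    assigned: set[str] = set()
    clusters: list[UIDCluster] = []
    for seed in order:
        if seed in assigned:
            continue
        members = [seed]
        assigned.add(seed)
        queue = [seed]
        while queue:
            x = queue.pop(0)
            cx = uid_counts[x]
            for y in sorted(nbrs[x], key=lambda u: (-uid_counts[u], u)):
                if y in assigned:
                    continue
                if cx >= 2 * uid_counts[y] - 1:
                    assigned.add(y)
                    members.append(y)
                    queue.append(y)
        clusters.append(
            UIDCluster(
                canonical=seed,
                uids=tuple(members),
                size=sum(uid_counts[u] for u in members),
            )
        )
    return clusters


def cluster_uids_exact(uid_counts: Mapping[str, int]) -> list[UIDCluster]:
    """Naive clustering: one cluster per distinct UID string."""
    order = sorted(uid_counts, key=lambda u: (-uid_counts[u], u))
    return [UIDCluster(canonical=u, uids=(u,), size=uid_counts[u]) for u in order]


def build_consensus(
    sequences: Sequence[str], min_family_size: int = 3
) -> str | None:
    """Per-position majority vote over family member sequences.

    Members must already be aligned at their shared 5' coordinate (offset 0
    of every string).  Families smaller than ``min_family_size`` are
    rejected (returns None).  Ties and positions where no A/C/G/T vote
    exists yield ``N``.  The consensus length is the shortest member length.
    """
    if not sequences:
        raise ValueError("cannot build a consensus from an empty family")
    if len(sequences) < min_family_size:
        return None
    length = min(len(s) for s in sequences)
    arr = np.frombuffer(
        b"".join(s[:length].encode("ascii") for s in sequences), dtype=np.uint8
    ).reshape(len(sequences), length)
    counts = np.empty((4, length), dtype=np.int32)
    for b in range(4):
        counts[b] = (arr == _BASES[b]).sum(axis=0)
    top = counts.max(axis=0)
    winner = np.frombuffer(_BASES, dtype=np.uint8)[counts.argmax(axis=0)].copy()
    tied = (counts == top).sum(axis=0) > 1
    winner[tied | (top == 0)] = ord("N")
    return winner.tobytes().decode("ascii")


def collapse_reads(
    reads: Sequence[TaggedRead],
    mode: str = "directional",
    min_family_size: int = 3,
) -> tuple[list[UIDFamily], list[ConsensusRead]]:
    """Full grouping -> clustering -> consensus pipeline for one sample.

    ``mode`` selects the UID clustering: ``"directional"`` (error-tolerant)
    or ``"exact"`` (each distinct UID string is its own family).  Every
    accepted read is assigned to exactly one family; only families of at
    least ``min_family_size`` reads produce a consensus read.
    """
    if mode not in ("directional", "exact"):
        raise ValueError(f"unknown clustering mode: {mode!r}")
    cluster_fn = cluster_uids_directional if mode == "directional" else cluster_uids_exact
    groups = group_by_position(reads)
    families: list[UIDFamily] = []
    consensus_reads: list[ConsensusRead] = []
    for key in sorted(groups):
        chrom, pos, strand = key
        by_uid = groups[key]
        uid_counts = {u: len(v) for u, v in by_uid.items()}
        for cluster in cluster_fn(uid_counts):
            member_idx = [i for u in cluster.uids for i in by_uid[u]]
            family = UIDFamily(
                chrom=chrom,
                pos=pos,
                strand=strand,
                uid=cluster.canonical,
                member_read_ids=tuple(reads[i].read_id for i in member_idx),
                size=len(member_idx),
            )
            if family.size >= min_family_size:
                seqs = [reads[i].sequence for i in member_idx]
                if strand == "-":
                    # 5' end of a minus-strand read is its right end: align
                    # from the right, then restore reference orientation.
                    cons = build_consensus([s[::-1] for s in seqs], min_family_size)
                    cons = cons[::-1] if cons is not None else None
                else:
                    cons = build_consensus(seqs, min_family_size)
                if cons is not None:
                    family.consensus = ConsensusRead(
                        chrom=chrom,
                        pos=pos,
                        strand=strand,
                        uid=cluster.canonical,
                        sequence=cons,
                        family_size=family.size,
                    )
                    consensus_reads.append(family.consensus)
            families.append(family)
    return families, consensus_reads


def family_statistics(
    families: Sequence[UIDFamily], total_raw_reads: int
) -> FamilyStats:
    """Read-weighted family-size composition (small / optimal / large bands)."""
    if total_raw_reads <= 0:
        raise ValueError("total_raw_reads must be positive")
    if not families:
        raise ValueError("no families given")
    sizes = np.array([f.size for f in families])
    assigned = int(sizes.sum())
    small = int(sizes[sizes <= 2].sum())
    optimal = int(sizes[(sizes >= 3) & (sizes <= 50)].sum())
    large = int(sizes[sizes > 50].sum())
    n_consensus = sum(1 for f in families if f.consensus is not None)
    return FamilyStats(
        n_raw_reads=total_raw_reads,
        n_families=len(families),
        n_consensus=n_consensus,
        fraction_small=small / assigned,
        fraction_optimal=optimal / assigned,
        fraction_large=large / assigned,
        mean_family_size=assigned / len(families),
        families_per_million_raw=len(families) / total_raw_reads * 1e6,
        unique_per_raw=n_consensus / total_raw_reads,
    )
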