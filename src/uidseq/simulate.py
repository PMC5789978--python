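"""Synthetic UID-tagged cfDNA sequencing data with full ground truth.

The generative model mirrors the physics of a UID-based targeted library:

1. *Fragmentation* — ``n_fragments`` cfDNA molecules are drawn with start
   positions inside the enriched panel regions (or off target with
   probability ``1 - on_target_prob``) and lengths from a truncated normal
   (default mean 166 bp, sd 40 bp, the canonical cfDNA fragment size).
2. *UID tagging* — each molecule receives a UID of ``uid_length`` random
   nucleotides (six by default, i.e. 4096 distinct tags), attached before
   any amplification so that every PCR copy inherits it.
3. *PCR* — a per-cycle Bernoulli branching process: in each of
   ``pcr_cycles`` cycles every molecule duplicates with probability
   ``eff_i * max(0, 1 - N/K)`` where ``eff_i`` is a fragment-specific
   amplification efficiency (mean ``pcr_efficiency``, spread
   ``pcr_efficiency_sd`` — amplification bias) and ``K`` the carrying
   capacity modelling reagent exhaustion.  ``split_reactions=2`` halves the
   input into two independent reactions, each with its own capacity, and
   merges the products.  Each duplication introduces polymerase errors at
   ``polymerase_error_rate`` per base over insert and UID.
4. *Sequencing* — ``reads_sequenced`` molecules are drawn uniformly with
   replacement from the amplified pool; each emitted read receives
   independent substitution errors at ``seq_error_rate`` (insert) and
   ``uid_error_rate`` (UID) and is truncated to ``read_length`` from its
   5' end.

Tumor-derived variants are spiked by giving each fragment overlapping a
spiked site the alternate allele with probability ``allele_fraction``.

Every emitted read has exactly one record in the returned truth table
(fragment identity, true UID, true mapping key, sequencing-stage errors,
tumor origin), which downstream tests use as an oracle.  All randomness
derives from the single ``seed`` in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import TaggedRead, UIDFamily

_BASES = b"ACGT"

#: Hard safety cap on the molecule pool (prevents runaway memory).
HARD_POOL_CAP = 20_000_000

_MIN_FRAGMENT_LENGTH = 30


@dataclass(frozen=True)
class SpikedMutation:
    """A known tumor variant injected into the simulation.

    ``allele_fraction`` is the probability that a fragment overlapping
    ``pos`` carries the alternate allele; if None, the config-level
    ``tumor_fraction`` is used.
    """

    pos: int
    ref: str
    alt: str
    allele_fraction: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library preparation + sequencing run.

    Defaults are a scaled-down but proportionate rendition of a deep
    targeted cfDNA experiment: a 30 kb panel sequenced to ~2000x raw depth
    that collapses to ~250x unique coverage, with PCR cycle counts in the
    19-25 range used for such libraries.
    """

    reference_length: int = 40_000
    panel_regions: tuple[tuple[int, int], ...] = ((5_000, 35_000),)
    n_fragments: int = 50_000
    fragment_length_mean: float = 166.0
    fragment_length_sd: float = 40.0
    uid_length: int = 6
    pcr_cycles: int = 21
    pcr_efficiency: float = 0.55
    pcr_efficiency_sd: float = 0.08
    carrying_capacity: int | None = 1_500_000
    split_reactions: int = 1
    polymerase_error_rate: float = 1e-5
    seq_error_rate: float = 1e-3
    uid_error_rate: float = 1e-3
    tumor_fraction: float = 0.0
    spiked_mutations: tuple[SpikedMutation, ...] = ()
    reads_sequenced: int = 400_000
    read_length: int | None = 150
    on_target_prob: float = 0.95
    sampling: str = "with_replacement"
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "pcr_efficiency",
            "polymerase_error_rate",
            "seq_error_rate",
            "uid_error_rate",
            "tumor_fraction",
            "on_target_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be >= 0")
        if self.uid_length < 1:
            raise ValueError("uid_length must be >= 1")
        if self.split_reactions not in (1, 2):
            raise ValueError("split_reactions must be 1 or 2")
        if self.n_fragments < 0 or self.reads_sequenced < 0:
            raise ValueError("counts must be non-negative")
        if self.sampling not in ("with_replacement", "without_replacement"):
            raise ValueError(f"unknown sampling mode: {self.sampling!r}")
        if not self.panel_regions:
            raise ValueError("at least one panel region is required")
        for start, end in self.panel_regions:
            if not (0 <= start < end <= self.reference_length):
                raise ValueError(f"panel region ({start}, {end}) outside reference")
        for m in self.spiked_mutations:
            af = m.allele_fraction
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"spiked allele fraction {af} outside [0, 1]")
            if not 0 <= m.pos < self.reference_length:
                raise ValueError(f"spiked position {m.pos} outside reference")

    @property
    def uid_space_size(self) -> int:
        """Number of distinct UID sequences (4^uid_length)."""
        return 4 ** self.uid_length


@dataclass(slots=True)
class Fragment:
    """One original (pre-PCR) tagged cfDNA molecule."""

    fragment_id: int
    start: int       # leftmost reference coordinate (0-based)
    length: int
    strand: str
    uid: str
    sequence: str    # reference orientation, tumor alleles applied
    is_tumor: bool

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' mapping coordinate (what reads are grouped on)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class MoleculePool:
    """Amplified molecule pool: parallel arrays over molecules.

    UID and insert sequences are stored as bytes and shared between a copy
    and its parent unless a polymerase error was introduced.
    """

    fragments: list[Fragment]
    frag_idx: np.ndarray          # fragment index per molecule
    uids: list[bytes]
    seqs: list[bytes]

    def __len__(self) -> int:
        return len(self.uids)


def reference_sequence(config: SimConfig) -> str:
    """Deterministic random reference for this config's seed."""
    rng = np.random.default_rng([config.seed, 0])
    codes = rng.integers(0, 4, config.reference_length)
    return np.frombuffer(_BASES, dtype=np.uint8)[codes].tobytes().decode("ascii")


def _complement_intervals(
    regions: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    merged = sorted(regions)
    out, cursor = [], 0
    for start, end in merged:
        if start > cursor:
            out.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < length:
        out.append((cursor, length))
    return out


def sample_fragments(config: SimConfig) -> list[Fragment]:
    """Draw the original tagged molecules (stage 1 + 2 of the model)."""
    ref = reference_sequence(config)
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_fragments
    if n == 0:
        return []

    lo = (_MIN_FRAGMENT_LENGTH - config.fragment_length_mean) / config.fragment_length_sd
    hi = (config.reference_length - config.fragment_length_mean) / config.fragment_length_sd
    lengths = stats.truncnorm.rvs(
        lo, hi,
        loc=config.fragment_length_mean,
        scale=config.fragment_length_sd,
        size=n,
        random_state=rng,
    ).astype(np.int64)

    regions = list(config.panel_regions)
    widths = np.array([e - s for s, e in regions], dtype=float)
    off_regions = _complement_intervals(regions, config.reference_length)
    off_widths = np.array([e - s for s, e in off_regions], dtype=float)
    on_target = rng.random(n) < config.on_target_prob
    if not len(off_regions):
        on_target[:] = True

    uid_codes = rng.integers(0, 4, (n, config.uid_length))
    base_lut = np.frombuffer(_BASES, dtype=np.uint8)
    uid_strings = [
        base_lut[row].tobytes().decode("ascii") for row in uid_codes
    ]
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # Vectorized placement: pick a region (length-weighted) and a uniform
    # start inside it for every fragment up front.
    on_choice = rng.choice(len(regions), size=n, p=widths / widths.sum())
    if len(off_regions):
        off_choice = rng.choice(
            len(off_regions), size=n, p=off_widths / off_widths.sum()
        )
    else:
        off_choice = np.zeros(n, dtype=np.int64)
    u_start = rng.random(n)

    mutations = config.spiked_mutations
    frags: list[Fragment] = []
    for i in range(n):
        if on_target[i]:
            r_start, r_end = regions[on_choice[i]]
        else:
            r_start, r_end = off_regions[off_choice[i]]
        start = r_start + int(u_start[i] * (r_end - r_start))
        end = min(start + int(lengths[i]), config.reference_length)  # clip at edge
        seq = ref[start:end]
        is_tumor = False
        for m in mutations:
            if start <= m.pos < end:
                af = m.allele_fraction
                if af is None:
                    af = config.tumor_fraction
                if rng.random() < af:
                    off = m.pos - start
                    seq = seq[:off] + m.alt + seq[off + 1:]
                    is_tumor = True
        frags.append(
            Fragment(
                fragment_id=i,
                start=start,
                length=end - start,
                strand=str(strands[i]),
                uid=uid_strings[i],
                sequence=seq,
                is_tumor=is_tumor,
            )
        )
    return frags


def _mutate_bytes(data: bytes, positions: np.ndarray, rng: np.random.Generator) -> bytes:
    buf = bytearray(data)
    for p in positions:
        old = buf[p]
        choices = [b for b in _BASES if b != old]
        buf[p] = choices[rng.integers(0, len(choices))]
    return bytes(buf)


def _amplify_one_reaction(
    pool_frag_idx: np.ndarray,
    uids: list[bytes],
    seqs: list[bytes],
    eff_frag: np.ndarray,
    frag_len: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[bytes], list[bytes]]:
    K = config.carrying_capacity
    p_err = config.polymerase_error_rate
    uid_len = config.uid_length
    frag_idx = list(pool_frag_idx)
    for _ in range(config.pcr_cycles):
        N = len(uids)
        if N == 0:
            break
        fidx = np.asarray(frag_idx, dtype=np.int64)
        cap = max(0.0, 1.0 - N / K) if K else 1.0
        if cap == 0.0:
            continue
        eff = eff_frag[fidx] * cap
        dup = np.flatnonzero(rng.random(N) < eff)
        if N + dup.size > HARD_POOL_CAP:
            raise RuntimeError(
                f"molecule pool would exceed the hard cap of {HARD_POOL_CAP}; "
                "lower pcr_cycles/pcr_efficiency or set a carrying capacity"
            )
        if p_err > 0:
            n_err = rng.binomial(frag_len[fidx[dup]] + uid_len, p_err)
        else:
            n_err = np.zeros(dup.size, dtype=np.int64)
        for j, i in enumerate(dup):
            uid, seq = uids[i], seqs[i]
            if n_err[j]:
                # errors land uniformly over UID + insert
                total = uid_len + len(seq)
                pos = rng.integers(0, total, n_err[j])
                uid_pos = pos[pos < uid_len]
                seq_pos = pos[pos >= uid_len] - uid_len
                if uid_pos.size:
                    uid = _mutate_bytes(uid, uid_pos, rng)
                if seq_pos.size:
                    seq = _mutate_bytes(seq, seq_pos, rng)
            uids.append(uid)
            seqs.append(seq)
            frag_idx.append(int(fidx[i]))
    return np.asarray(frag_idx, dtype=np.int64), uids, seqs


def amplify(fragments: Sequence[Fragment], config: SimConfig) -> MoleculePool:
    """PCR-amplify tagged molecules (stage 3 of the model).

    Returns the final molecule pool.  With ``split_reactions=2`` the input
    is split at random into two halves amplified independently, each with
    its own carrying capacity, then merged — the modelled mechanism behind
    the empirical benefit of split amplification for library complexity.
    """
    rng = np.random.default_rng([config.seed, 2])
    n = len(fragments)
    fragments = list(fragments)
    # Fragment-intrinsic amplification efficiency (bias): Beta with mean
    # pcr_efficiency and sd pcr_efficiency_sd.
    m, s = config.pcr_efficiency, config.pcr_efficiency_sd
    if s > 0 and 0 < m < 1:
        v = min(s * s, 0.95 * m * (1 - m))
        k = m * (1 - m) / v - 1
        eff_frag = rng.beta(m * k, (1 - m) * k, n)
    else:
        eff_frag = np.full(n, m)
    frag_len = np.array([f.length for f in fragments], dtype=np.int64)

    order = rng.permutation(n)
    halves = (
        [order]
        if config.split_reactions == 1
        else [order[: n // 2], order[n // 2 :]]
    )
    all_idx: list[np.ndarray] = []
    all_uids: list[bytes] = []
    all_seqs: list[bytes] = []
    for part in halves:
        uids = [fragments[i].uid.encode("ascii") for i in part]
        seqs = [fragments[i].sequence.encode("ascii") for i in part]
        fidx, uids, seqs = _amplify_one_reaction(
            np.asarray(part, dtype=np.int64), uids, seqs, eff_frag, frag_len, config, rng
        )
        all_idx.append(fidx)
        all_uids.extend(uids)
        all_seqs.extend(seqs)
    return MoleculePool(
        fragments=fragments,
        frag_idx=np.concatenate(all_idx) if all_idx else np.empty(0, dtype=np.int64),
        uids=all_uids,
        seqs=all_seqs,
    )


def sequence_reads(
    pool: MoleculePool, config: SimConfig
) -> tuple[list[TaggedRead], pd.DataFrame]:
    """Sample reads from the pool (stage 4) and attach the truth table.

    The truth table has one row per emitted read: ``read_id``,
    ``fragment_id``, ``uid`` (the true, pre-error UID), ``chrom``, ``pos``
    (true 5' coordinate), ``strand``, ``tumor`` and the sequencing-stage
    substitutions in ``seq_errors`` / ``uid_errors`` (``offset:FROM>TO``
    separated by ``;``).  PCR-introduced errors are embedded in the
    molecule sequences themselves and surface as differences from the
    fragment's true sequence.
    """
    R = config.reads_sequenced
    if R == 0:
        return [], _empty_truth()
    if len(pool) == 0:
        raise ValueError("cannot sequence from an empty molecule pool")
    rng = np.random.default_rng([config.seed, 3])
    if config.sampling == "with_replacement":
        # proportional cluster sampling: valid when the pool is much larger
        # than the read budget
        idx = rng.integers(0, len(pool), R)
    else:
        # each read consumes one distinct physical molecule, so yield is
        # capped by library complexity (the pool size)
        R = min(R, len(pool))
        idx = rng.permutation(len(pool))[:R]

    lens = np.array([len(pool.seqs[i]) for i in idx], dtype=np.int64)
    if config.read_length is not None:
        lens = np.minimum(lens, config.read_length)
    n_seq_err = (
        rng.binomial(lens, config.seq_error_rate)
        if config.seq_error_rate > 0
        else np.zeros(R, dtype=np.int64)
    )
    n_uid_err = (
        rng.binomial(config.uid_length, config.uid_error_rate, R)
        if config.uid_error_rate > 0
        else np.zeros(R, dtype=np.int64)
    )

    reads: list[TaggedRead] = []
    truth: dict[str, list] = {
        "read_id": [], "fragment_id": [], "uid": [], "chrom": [],
        "pos": [], "strand": [], "tumor": [], "seq_errors": [], "uid_errors": [],
    }
    for r in range(R):
        j = int(idx[r])
        frag = pool.fragments[int(pool.frag_idx[j])]
        seq = pool.seqs[j]
        L = int(lens[r])
        # sequencing proceeds from the 5' end of the molecule
        seq = seq[:L] if frag.strand == "+" else seq[len(seq) - L :]
        uid = pool.uids[j]
        seq_err_rec, uid_err_rec = "", ""
        if n_seq_err[r]:
            buf = bytearray(seq)
            recs = []
            for p in rng.integers(0, L, n_seq_err[r]):
                old = buf[p]
                choices = [b for b in _BASES if b != old]
                new = choices[rng.integers(0, 3)]
                buf[p] = new
                recs.append(f"{p}:{chr(old)}>{chr(new)}")
            seq = bytes(buf)
            seq_err_rec = ";".join(recs)
        if n_uid_err[r]:
            buf = bytearray(uid)
            recs = []
            for p in rng.integers(0, config.uid_length, n_uid_err[r]):
                old = buf[p]
                choices = [b for b in _BASES if b != old]
                new = choices[rng.integers(0, 3)]
                buf[p] = new
                recs.append(f"{p}:{chr(old)}>{chr(new)}")
            uid = bytes(buf)
            uid_err_rec = ";".join(recs)
        read_id = f"r{r}"
        pos = frag.start if frag.strand == "+" else frag.start + len(pool.seqs[j]) - 1
        reads.append(
            TaggedRead(
                read_id=read_id,
                chrom=config.chrom,
                pos=pos,
                strand=frag.strand,
                uid=uid.decode("ascii"),
                sequence=seq.decode("ascii"),
            )
        )
        truth["read_id"].append(read_id)
        truth["fragment_id"].append(frag.fragment_id)
        truth["uid"].append(frag.uid)
        truth["chrom"].append(config.chrom)
        truth["pos"].append(frag.five_prime)
        truth["strand"].append(frag.strand)
        truth["tumor"].append(frag.is_tumor)
        truth["seq_errors"].append(seq_err_rec)
        truth["uid_errors"].append(uid_err_rec)
    return reads, pd.DataFrame(truth)


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "fragment_id": pd.Series(dtype=np.int64),
            "uid": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "tumor": pd.Series(dtype=bool),
            "seq_errors": pd.Series(dtype=str),
            "uid_errors": pd.Series(dtype=str),
        }
    )


def simulate_reads(config: SimConfig) -> tuple[list[TaggedRead], pd.DataFrame, list[Fragment]]:
    """Run the full generative model: fragments -> PCR -> reads + truth."""
    fragments = sample_fragments(config)
    if not fragments:
        return [], _empty_truth(), []
    pool = amplify(fragments, config)
    reads, truth = sequence_reads(pool, config)
    return reads, truth, fragments


@dataclass(frozen=True)
class TruthRecovery:
    """How well consensus reads recover the true original fragments."""

    n_consensus: int
    n_pure: int            # families whose members all share one fragment
    n_one_to_one: int      # pure families whose fragment has no other family
    rate: float            # n_one_to_one / n_consensus


def truth_recovery(families: Sequence[UIDFamily], truth: pd.DataFrame) -> TruthRecovery:
    """Truth-table oracle: fraction of consensus reads mapping 1-to-1 onto
    true original fragments."""
    read_to_frag = dict(zip(truth["read_id"], truth["fragment_id"]))
    frag_claims: dict[int, int] = {}
    fam_frag: list[tuple[UIDFamily, set[int]]] = []
    for fam in families:
        if fam.consensus is None:
            continue
        frags = {read_to_frag[rid] for rid in fam.member_read_ids}
        fam_frag.append((fam, frags))
        if len(frags) == 1:
            fid = next(iter(frags))
            frag_claims[fid] = frag_claims.get(fid, 0) + 1
    n_consensus = len(fam_frag)
    n_pure = sum(1 for _, frags in fam_frag if len(frags) == 1)
    n_one = sum(
        1
        for _, frags in fam_frag
        if len(frags) == 1 and frag_claims[next(iter(frags))] == 1
    )
    if n_consensus == 0:
        raise ValueError("no consensus reads to evaluate")
    return TruthRecovery(
        n_consensus=n_consensus,
        n_pure=n_pure,
        n_one_to_one=n_one,
        rate=n_one / n_consensus,
    )
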