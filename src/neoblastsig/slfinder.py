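"""De novo trans-splice-leader discovery from transcript 5' ends.

Many flatworm mRNAs begin with a short spliced-leader (SL) RNA added by
trans-splicing, visible in an assembly as a shared 5' motif.  The leader is
recovered without prior knowledge by counting k-mers (default k = 19) in the
first 100 nt of every transcript — each k-mer counted once per transcript, so
internal repeats cannot outcompete a shared prefix — and greedily walking the
overlap graph of high-frequency k-mers into a consensus.  Transcripts are then
classified as trans-spliced by searching their 5' window for a suffix of the
consensus (assembly truncation often leaves only a partial leader).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGT")


class SLError(ValueError):
    pass


@dataclass
class KmerCensus:
    k: int
    window: int
    counts: Counter
    n_transcripts: int


@dataclass
class LeaderCall:
    """Consensus leader with its supporting k-mer path."""

    consensus: str
    support: int
    kmers: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class TransSpliceFlags:
    flags: dict[str, bool]
    details: dict[str, tuple[int, int, int]]  # id -> (match_len, match_start, mismatches)
    min_match_len: int
    max_mismatch: int
    search_window: int


def _seq_of(rec) -> str:
    return str(rec.seq).upper() if isinstance(rec, SeqRecord) else str(rec).upper()


def kmer_census(transcripts, k: int = 19, window: int = 100) -> KmerCensus:
    """Count, per k-mer, the number of distinct transcripts whose 5' window holds it."""
    if k < 2:
        raise SLError("k must be >= 2")
    if window < k:
        raise SLError("window must be >= k")
    counts: Counter = Counter()
    n = 0
    for rec in transcripts:
        n += 1
        seq = _seq_of(rec)[:window]
        seen = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= _ALPHABET:
                seen.add(kmer)
        counts.update(seen)
    return KmerCensus(k=k, window=window, counts=counts, n_transcripts=n)


def _frequent_neighbors(kmer: str, frequent: dict, side: str) -> list[str]:
    if side == "right":
        stem = kmer[1:]
        cands = [stem + b for b in "ACGT"]
    else:
        stem = kmer[:-1]
        cands = [b + stem for b in "ACGT"]
    return [c for c in cands if c in frequent and c != kmer]


def reconstruct_leader(census: KmerCensus, min_frequency: int | None = None) -> LeaderCall:
    """Greedy consensus from overlapping frequent k-mers.

    Starting from the most frequent k-mer, extend right and then left while a
    unique frequent neighbor overlaps by k - 1; stop on a branch (two or more
    frequent neighbors) or a dead end.  Default threshold: max(10, 1% of
    transcripts).  Returns an empty consensus when nothing is frequent.
    """
    if min_frequency is None:
        min_frequency = max(10, int(np.ceil(0.01 * census.n_transcripts)))
    if min_frequency <= 0:
        raise SLError("min_frequency must be positive")
    frequent = {km: c for km, c in census.counts.items() if c >= min_frequency}
    if not frequent:
        return LeaderCall(consensus="", support=0)

    seed = min(frequent, key=lambda km: (-frequent[km], km))
    path = [seed]
    used = {seed}
    cur = seed
    while True:
        nbrs = [n for n in _frequent_neighbors(cur, frequent, "right") if n not in used]
        if len(nbrs) != 1:
            break
        cur = nbrs[0]
        path.append(cur)
        used.add(cur)
    cur = seed
    while True:
        nbrs = [n for n in _frequent_neighbors(cur, frequent, "left") if n not in used]
        if len(nbrs) != 1:
            break
        cur = nbrs[0]
        path.insert(0, cur)
        used.add(cur)

    consensus = path[0] + "".join(km[-1] for km in path[1:])
    support = min(frequent[km] for km in path)
    return LeaderCall(
        consensus=consensus, support=support, kmers=[(km, frequent[km]) for km in path]
    )


def frequent_paths(census: KmerCensus, min_frequency: int | None = None) -> list[LeaderCall]:
    """All maximal unique-extension paths over frequent k-mers, for manual review."""
    if min_frequency is None:
        min_frequency = max(10, int(np.ceil(0.01 * census.n_transcripts)))
    frequent = dict(census.counts)
    frequent = {km: c for km, c in frequent.items() if c >= min_frequency}
    calls: list[LeaderCall] = []
    remaining = dict(frequent)
    while remaining:
        sub_census = KmerCensus(census.k, census.window, Counter(remaining), census.n_transcripts)
        call = reconstruct_leader(sub_census, min_frequency)
        if not call.consensus:
            break
        calls.append(call)
        for km, _ in call.kmers:
            remaining.pop(km, None)
    return calls


_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def _encode(seq: str, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.int8)
    for i, b in enumerate(seq[:length]):
        arr[i] = _BASE_CODE.get(b, 0)
    return arr


def classify_transspliced(
    transcripts,
    leader: str,
    min_match_len: int = 15,
    max_mismatch: int = 1,
    search_window: int = 30,
) -> TransSpliceFlags:
    """Flag transcripts whose 5' window carries a leader suffix.

    A transcript is trans-spliced when some suffix of the leader of length >=
    min_match_len aligns, ungapped, starting within the first search_window nt
    with <= max_mismatch mismatches.  The leftmost match wins; at a given
    start the longest matching suffix is reported.
    """
    leader = leader.upper()
    if not leader:
        raise SLError("leader must be non-empty")
    if len(leader) < min_match_len:
        raise SLError("leader shorter than min_match_len")

    llen = len(leader)
    lead_arr = _encode(leader, llen)
    span = search_window + llen
    ids, rows, lengths = [], [], []
    for rec in transcripts:
        seq = _seq_of(rec)
        ids.append(rec.id if isinstance(rec, SeqRecord) else f"seq{len(ids)}")
        rows.append(_encode(seq, span))
        lengths.append(len(seq))
    if not ids:
        return TransSpliceFlags({}, {}, min_match_len, max_mismatch, search_window)
    mat = np.stack(rows)  # padding code 0 never matches a base
    lengths = np.array(lengths)

    flags = np.zeros(len(ids), dtype=bool)
    details: dict[str, tuple[int, int, int]] = {}
    for start in range(search_window):
        pending = ~flags
        if not pending.any():
            break
        for match_len in range(llen, min_match_len - 1, -1):
            if start + match_len > span:
                continue
            suffix = lead_arr[llen - match_len :]
            seg = mat[:, start : start + match_len]
            mism = (seg != suffix).sum(axis=1)
            hit = pending & (mism <= max_mismatch) & (lengths >= start + match_len)
            for idx in np.nonzero(hit)[0]:
                details[ids[idx]] = (match_len, start, int(mism[idx]))
            flags |= hit
            pending &= ~hit
    flag_map = {tid: bool(flags[i]) for i, tid in enumerate(ids)}
    return TransSpliceFlags(flag_map, details, min_match_len, max_mismatch, search_window)
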