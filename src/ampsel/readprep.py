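"""Raw paired FASTQ to per-sample merged amplicon sequences.

Stages, in order: dual-index demultiplexing, adapter/quality trimming,
overlap merging of the mate pair, and the 80-bp length filter that removes
primer dimers. Allele identity downstream is the merged-read *length*, so
every stage here is substitution-only — nothing may insert or delete bases
except at the read ends.

The merger is internal and mirrors the behaviour of overlap-based mergers
used on short amplicons: it searches all relative placements of read 2
(reverse-complemented) against read 1, including "outie"/staggered
placements where the insert is shorter than the read length, accepts the
longest overlap whose mismatch density is at most ``max_mismatch_density``
(default 0.05), and resolves disagreeing overlap bases to the
higher-quality base. In the outie case the dovetail overhangs are adapter
read-through, so only the overlap region is kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import StageError
from .panel import MarkerPanel
from .seq import hamming, revcomp

DEFAULT_MIN_LENGTH = 80  # primer dimers and junk sit below this
DEFAULT_Q_THRESHOLD = 20
_MIN_ADAPTER_OVERLAP = 6


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    i5_observed: str
    i7_observed: str


@dataclass
class MergedRead:
    sample_id: str
    sequence: str
    length: int
    mean_quality: float


@dataclass
class PrepStats:
    """Read-conservation ledger for one demultiplex + merge run."""

    n_input: int = 0
    n_unassigned: int = 0
    per_sample: dict = field(default_factory=dict)  # sample_id -> stage counts

    def sample_entry(self, sample_id: str) -> dict:
        return self.per_sample.setdefault(
            sample_id,
            {"assigned": 0, "trim_dropped": 0, "merge_failed": 0, "length_filtered": 0, "kept": 0},
        )


# ---------------------------------------------------------------------------
# FASTQ input


def _indexes_from_header(title: str) -> tuple[str, str]:
    # Illumina-style comment: "<id> 1:N:0:<i5>+<i7>"
    try:
        comment = title.split(None, 1)[1]
        idx = comment.rsplit(":", 1)[1]
        i5, i7 = idx.split("+")
        return i5, i7
    except (IndexError, ValueError):
        raise StageError("demux", f"no index information in read header {title!r}")


def iter_read_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    index_paths: tuple[str | Path, str | Path] | None = None,
) -> "itertools.chain[ReadPair]":
    """Stream read pairs, taking indexes from headers or separate index reads."""

    def gen():
        with open(r1_path) as f1, open(r2_path) as f2:
            it1 = FastqGeneralIterator(f1)
            it2 = FastqGeneralIterator(f2)
            if index_paths is None:
                for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
                    i5, i7 = _indexes_from_header(t1)
                    yield ReadPair(t1.split(None, 1)[0], s1, q1, s2, q2, i5, i7)
            else:
                with open(index_paths[0]) as fi1, open(index_paths[1]) as fi2:
                    ii1 = FastqGeneralIterator(fi1)
                    ii2 = FastqGeneralIterator(fi2)
                    for (t1, s1, q1), (t2, s2, q2), (_, x5, _q5), (_, x7, _q7) in zip(
                        it1, it2, ii1, ii2
                    ):
                        yield ReadPair(t1.split(None, 1)[0], s1, q1, s2, q2, x5, x7)

    return gen()


# ---------------------------------------------------------------------------
# Demultiplexing


def make_index_matcher(panel: MarkerPanel, max_index_mismatch: int = 0):
    """Return a function mapping observed (i5, i7) to a sample_id or None.

    A pair is assigned iff both indexes match one sample's pair within the
    mismatch tolerance; among samples within tolerance the strictly
    smallest total distance wins, and an exact tie (equidistant samples)
    stays unassigned.
    """
    exact = {(s.i5_index, s.i7_index): s.sample_id for s in panel.samples}
    samples = panel.samples

    def match(i5: str, i7: str):
        hit = exact.get((i5, i7))
        if hit is not None or max_index_mismatch == 0:
            return hit
        best, best_d, tied = None, None, False
        for s in samples:
            if len(i5) != len(s.i5_index) or len(i7) != len(s.i7_index):
                continue
            d5 = hamming(i5, s.i5_index, max_index_mismatch)
            if d5 > max_index_mismatch:
                continue
            d7 = hamming(i7, s.i7_index, max_index_mismatch)
            if d7 > max_index_mismatch:
                continue
            total = d5 + d7
            if best_d is None or total < best_d:
                best, best_d, tied = s.sample_id, total, False
            elif total == best_d:
                tied = True
        return None if tied else best

    return match


def demux_by_index(
    pairs, panel: MarkerPanel, max_index_mismatch: int = 0
) -> dict[str, list[ReadPair]]:
    """Partition read pairs by sample; unmatched pairs land in "unassigned"."""
    match = make_index_matcher(panel, max_index_mismatch)
    out: dict[str, list[ReadPair]] = {s.sample_id: [] for s in panel.samples}
    out["unassigned"] = []
    for pair in pairs:
        sid = match(pair.i5_observed, pair.i7_observed)
        out[sid if sid is not None else "unassigned"].append(pair)
    return out


# ---------------------------------------------------------------------------
# Trimming


def trim_adapter(seq: str, qual: str, adapter: str) -> tuple[str, str]:
    """Remove an adapter read-through suffix (>= 6 nt overlap, <=1 mm / 10 nt).

    The adapter may occur internally (full match, rest of the read is
    downstream library structure) or as a partial prefix hanging off the
    3' end; everything from the adapter start onward is removed.
    """
    n, alen = len(seq), len(adapter)
    if n < _MIN_ADAPTER_OVERLAP or alen < _MIN_ADAPTER_OVERLAP:
        return seq, qual
    seed = adapter[: min(10, alen)]
    p = seq.find(seed)
    if p != -1:
        ov = min(alen, n - p)
        if ov >= _MIN_ADAPTER_OVERLAP and hamming(seq[p : p + ov], adapter[:ov], ov // 10) <= ov // 10:
            return seq[:p], qual[:p]
    # fallback: scan all placements, allowing mismatches in the seed region
    for p in range(0, n - _MIN_ADAPTER_OVERLAP + 1):
        ov = min(alen, n - p)
        budget = ov // 10
        if hamming(seq[p : p + ov], adapter[:ov], budget) <= budget:
            return seq[:p], qual[:p]
    return seq, qual


def quality_trim(
    seq: str,
    qual: str,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    adapter: str | None = None,
) -> tuple[str, str]:
    """Adapter-trim, then strip trailing bases below ``q_threshold`` (Phred+33)."""
    if adapter:
        seq, qual = trim_adapter(seq, qual, adapter)
    cut = len(qual)
    floor = q_threshold + 33
    while cut > 0 and ord(qual[cut - 1]) < floor:
        cut -= 1
    return seq[:cut], qual[:cut]


# ---------------------------------------------------------------------------
# Merging


def _count_mismatches(a: str, b: str, budget: int) -> int:
    if a == b:
        return 0
    return hamming(a, b, budget)


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.05,
    max_overlap: int = 150,
    sample_id: str = "",
) -> MergedRead | None:
    """Overlap-merge a mate pair; returns None when no admissible overlap exists.

    Searches all placements of revcomp(read 2) against read 1 in order of
    decreasing overlap length; the first admissible overlap (mismatch
    density <= ``max_mismatch_density``, length >= ``min_overlap``) wins,
    with ties on overlap length resolved toward fewer mismatches.
    """
    s1, q1 = pair.seq1, pair.qual1
    s2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return None

    # candidate placements d (offset of s2 start relative to s1 start),
    # ordered by overlap length descending, small |d| first
    cands: list[tuple[int, int]] = []
    for d in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        start, end = max(0, d), min(n1, d + n2)
        ov = end - start
        if ov >= min_overlap:
            cands.append((min(ov, max_overlap), d))
    cands.sort(key=lambda t: (-t[0], abs(t[1])))

    best: tuple[int, int, int] | None = None  # (ov, mism, d)
    for ov, d in cands:
        if best is not None and ov < best[0]:
            break
        start, end = max(0, d), min(n1, d + n2)
        budget = int((end - start) * max_mismatch_density)
        mism = _count_mismatches(s1[start:end], s2[start - d : end - d], budget)
        if mism > budget:
            continue
        if best is None or mism < best[1]:
            best = (ov, mism, d)
        if best[1] == 0:
            break
    if best is None:
        return None

    _, mism, d = best
    start, end = max(0, d), min(n1, d + n2)
    o1, o2 = s1[start:end], s2[start - d : end - d]
    if mism == 0:
        cons, cons_q = o1, q1[start:end]
    else:
        cons_chars = []
        consq_chars = []
        for i in range(end - start):
            a, b = o1[i], o2[i]
            qa, qb = q1[start + i], q2[start - d + i]
            if a == b or qa >= qb:
                cons_chars.append(a)
                consq_chars.append(qa)
            else:
                cons_chars.append(b)
                consq_chars.append(qb)
        cons, cons_q = "".join(cons_chars), "".join(consq_chars)

    if d >= 0:
        seq = s1[:start] + cons + s2[end - d :]
        quals = q1[:start] + cons_q + q2[end - d :]
    else:
        # outie: overhangs on both sides are adapter read-through
        seq, quals = cons, cons_q
    mean_q = sum(ord(c) - 33 for c in quals) / len(quals) if quals else 0.0
    return MergedRead(sample_id=sample_id, sequence=seq, length=len(seq), mean_quality=mean_q)


# ---------------------------------------------------------------------------
# Length filter


def length_filter(
    reads: list[MergedRead], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[MergedRead], int]:
    """Keep reads of length >= ``min_length`` ("shorter than 80 bp" discarded).

    Returns (kept reads, number discarded).
    """
    kept = [r for r in reads if r.length >= min_length]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# Driver


def prep_reads(
    r1_path: str | Path,
    r2_path: str | Path,
    panel: MarkerPanel,
    max_index_mismatch: int = 0,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.05,
    min_length: int = DEFAULT_MIN_LENGTH,
    index_paths=None,
) -> tuple[dict[str, list[MergedRead]], PrepStats]:
    """Run demux → trim → merge → length filter over a paired FASTQ library.

    Returns per-sample merged reads plus a stage-by-stage conservation
    ledger: input == unassigned + Σ(assigned), and per sample
    assigned == kept + trim_dropped + merge_failed + length_filtered.
    """
    match = make_index_matcher(panel, max_index_mismatch)
    stats = PrepStats()
    merged: dict[str, list[MergedRead]] = {s.sample_id: [] for s in panel.samples}
    adapter1 = revcomp(panel.scheme.r2_tail)  # read 1 runs into rc(R2 tail)
    adapter2 = revcomp(panel.scheme.r1_tail)  # read 2 runs into rc(R1 tail)

    for pair in iter_read_pairs(r1_path, r2_path, index_paths):
        stats.n_input += 1
        sid = match(pair.i5_observed, pair.i7_observed)
        if sid is None:
            stats.n_unassigned += 1
            continue
        entry = stats.sample_entry(sid)
        entry["assigned"] += 1
        s1, q1 = quality_trim(pair.seq1, pair.qual1, q_threshold, adapter1)
        s2, q2 = quality_trim(pair.seq2, pair.qual2, q_threshold, adapter2)
        if not s1 or not s2:
            entry["trim_dropped"] += 1
            continue
        m = merge_pair(
            ReadPair(pair.read_id, s1, q1, s2, q2, pair.i5_observed, pair.i7_observed),
            min_overlap=min_overlap,
            max_mismatch_density=max_mismatch_density,
            sample_id=sid,
        )
        if m is None:
            entry["merge_failed"] += 1
            continue
        if m.length < min_length:
            entry["length_filtered"] += 1
            continue
        entry["kept"] += 1
        merged[sid].append(m)
    return merged, stats
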