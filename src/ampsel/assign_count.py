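"""Marker assignment, allele counting, top-allele extraction, and digital
electropherograms.

Merged reads are assigned to markers by their target primers: the read
prefix must match a marker's forward primer and the read suffix the
reverse complement of its reverse primer, each within a substitution
budget (no indels — primer bases are synthesis-fixed and length is the
allele). For SSR/indel/dominant markers the allele key is the full
primer-inclusive merged-read length in bp; for SNP markers reads are
stacked by exact sequence and the two most common haplotype stacks are
reported.

The per-(sample, marker) length histogram is the single source of every
downstream frequency: the four most common alleles (the Allele1–4/Freq1–4
report columns), the marker-assisted-selection target frequency, and the
digital electropherogram — a length-vs-frequency trace that mimics a
capillary electrophoresis trace and makes stutter ladders visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmpselError
from .panel import MarkerDef, MarkerPanel
from .readprep import MergedRead
from .seq import hamming, revcomp


@dataclass
class AlleleTable:
    """Histogram of allele observations for one (sample, marker).

    ``counts`` maps allele key -> read count; keys are bp lengths (int)
    for length-typed markers and haplotype sequences (str) for SNP markers.
    ``total_sample_reads`` is the sample's total read count entering
    assignment, the denominator for on-target proportions (not for allele
    frequencies, which use ``total_marker_reads``).
    """

    sample_id: str
    marker: str
    counts: dict = field(default_factory=dict)
    total_marker_reads: int = 0
    total_sample_reads: int = 0

    def add(self, allele, n: int = 1) -> None:
        self.counts[allele] = self.counts.get(allele, 0) + n
        self.total_marker_reads += n


@dataclass
class TopAlleles:
    """The <=4 most common alleles with frequencies over marker reads."""

    sample_id: str
    marker: str
    entries: list[tuple[object, int, float]] = field(default_factory=list)
    total_marker_reads: int = 0
    total_sample_reads: int = 0
    no_data: bool = False

    @property
    def frequencies(self) -> list[float]:
        return [f for _, _, f in self.entries]


@dataclass
class Electropherogram:
    sample_id: str
    marker: str
    trace: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class HaplotypeCatalog:
    """Named representative sequences (HAP1, HAP2, ...) for a SNP marker."""

    marker: str
    haplotypes: dict = field(default_factory=dict)  # name -> representative sequence

    def __post_init__(self) -> None:
        seqs = list(self.haplotypes.values())
        if len(set(seqs)) != len(seqs):
            raise AmpselError(f"catalog for {self.marker!r}: duplicate representative sequences")


# ---------------------------------------------------------------------------
# Assignment


class MarkerAssigner:
    """Precompiled both-ends primer matcher over a panel."""

    def __init__(self, panel: MarkerPanel, max_primer_mismatch: int = 2):
        self.max_mm = max_primer_mismatch
        self._markers = [
            (m.name, m.fwd_primer, revcomp(m.rev_primer), len(m.fwd_primer), len(m.rev_primer))
            for m in panel.markers
        ]
        self._by_name = {m.name: m for m in panel.markers}

    def assign(self, sequence: str) -> str | None:
        """Marker name for a merged read, or None when unassignable.

        Both ends must match the same marker; among qualifying markers the
        fewest total mismatches wins, and an exact tie is unassigned.
        """
        best_name, best_mm, tied = None, None, False
        for name, fwd, rev_rc, nf, nr in self._markers:
            if len(sequence) < nf + nr:
                continue
            mf = hamming(sequence[:nf], fwd, self.max_mm)
            if mf > self.max_mm:
                continue
            mr = hamming(sequence[-nr:], rev_rc, self.max_mm)
            if mr > self.max_mm:
                continue
            total = mf + mr
            if best_mm is None or total < best_mm:
                best_name, best_mm, tied = name, total, False
            elif total == best_mm:
                tied = True
        return None if tied else best_name


def assign_to_marker(
    read: MergedRead, panel: MarkerPanel, max_primer_mismatch: int = 2
) -> str | None:
    """One-shot wrapper around :class:`MarkerAssigner` (prefer the class in loops)."""
    return MarkerAssigner(panel, max_primer_mismatch).assign(read.sequence)


# ---------------------------------------------------------------------------
# Counting


def count_alleles(
    assigned_reads: list[tuple[MergedRead, str]], panel: MarkerPanel
) -> dict[tuple[str, str], AlleleTable]:
    """Tally allele observations per (sample, marker).

    Length-typed markers (SSR/indel/dominant) key on merged length; SNP
    markers key on the exact read sequence (haplotype stacking happens
    later). ``total_sample_reads`` is set to the number of assigned reads
    per sample plus whatever the caller adds for unassigned reads.
    """
    tables: dict[tuple[str, str], AlleleTable] = {}
    sample_totals: dict[str, int] = {}
    by_name = {m.name: m for m in panel.markers}
    for read, marker_name in assigned_reads:
        sample_totals[read.sample_id] = sample_totals.get(read.sample_id, 0) + 1
        key = (read.sample_id, marker_name)
        table = tables.get(key)
        if table is None:
            table = tables[key] = AlleleTable(sample_id=read.sample_id, marker=marker_name)
        marker = by_name[marker_name]
        table.add(read.sequence if marker.marker_class == "SNP" else read.length)
    for (sid, _), table in tables.items():
        table.total_sample_reads = sample_totals.get(sid, 0)
    return tables


def top_alleles(table: AlleleTable, k: int = 4) -> TopAlleles:
    """Extract the k most common alleles with frequencies over marker reads.

    Ordered by count descending; count ties break toward the smaller
    length (or lexicographically smaller sequence). An empty table yields
    a "no data" result rather than an error.
    """
    if table.total_marker_reads == 0:
        return TopAlleles(
            sample_id=table.sample_id,
            marker=table.marker,
            total_sample_reads=table.total_sample_reads,
            no_data=True,
        )
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    total = table.total_marker_reads
    return TopAlleles(
        sample_id=table.sample_id,
        marker=table.marker,
        entries=[(a, c, c / total) for a, c in ranked],
        total_marker_reads=total,
        total_sample_reads=table.total_sample_reads,
    )


# ---------------------------------------------------------------------------
# Haplotype stacking (SNP markers)


def stack_haplotypes(
    assigned_reads: list[tuple[MergedRead, str]],
    marker: MarkerDef,
    catalog: HaplotypeCatalog | None = None,
    k: int = 2,
) -> dict[str, TopAlleles]:
    """Stack SNP-marker reads by exact sequence; report top-k stacks per sample.

    Stacks are labelled by matching the catalog representatives at the
    marker's variant offsets when a catalog is given; otherwise HAP1,
    HAP2, ... by descending cohort-wide stack count. Sequencing errors
    create singleton stacks that never reach the top slots at realistic
    depths, so no alignment is needed.
    """
    if marker.marker_class != "SNP":
        raise AmpselError(f"stack_haplotypes requires a SNP marker, got {marker.marker_class}")

    per_sample: dict[str, dict[str, int]] = {}
    global_counts: dict[str, int] = {}
    for read, mname in assigned_reads:
        if mname != marker.name:
            continue
        per_sample.setdefault(read.sample_id, {})
        per_sample[read.sample_id][read.sequence] = (
            per_sample[read.sample_id].get(read.sequence, 0) + 1
        )
        global_counts[read.sequence] = global_counts.get(read.sequence, 0) + 1

    def label(seq: str) -> str:
        if catalog is not None:
            offs = marker.variant_offsets
            for name, rep in catalog.haplotypes.items():
                if len(seq) == len(rep) and all(
                    seq[o] == rep[o] for o in offs if o < len(rep)
                ):
                    return name
        return _global_names[seq]

    ranked_global = sorted(global_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    _global_names = {seq: f"HAP{i + 1}" for i, (seq, _) in enumerate(ranked_global)}

    out: dict[str, TopAlleles] = {}
    for sid, counts in per_sample.items():
        total = sum(counts.values())
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        out[sid] = TopAlleles(
            sample_id=sid,
            marker=marker.name,
            entries=[(label(seq), c, c / total) for seq, c in ranked],
            total_marker_reads=total,
        )
    return out


# ---------------------------------------------------------------------------
# Electropherogram export


def export_electropherogram(table: AlleleTable) -> Electropherogram:
    """Full length-frequency trace (zero-count lengths omitted), for SSR/indel.

    Unlike the top-4 report this keeps every observed length, which is what
    makes stutter ladders below a long-repeat allele visible.
    """
    trace: list[tuple[int, float]] = []
    total = table.total_marker_reads
    if total > 0:
        for length in sorted(table.counts):
            if not isinstance(length, int):
                raise AmpselError("electropherograms are defined for length-typed markers only")
            trace.append((length, table.counts[length] / total))
    return Electropherogram(sample_id=table.sample_id, marker=table.marker, trace=trace)


def plot_electropherogram(egram: Electropherogram, path) -> None:
    """Render a stick-trace plot of an electropherogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 2.5))
    if egram.trace:
        lengths, freqs = zip(*egram.trace)
        ax.vlines(lengths, 0, freqs, colors="tab:blue")
        ax.plot(lengths, freqs, "o", ms=3, color="tab:blue")
    ax.set_xlabel("allele length (bp)")
    ax.set_ylabel("frequency")
    ax.set_title(f"{egram.sample_id} / {egram.marker}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
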