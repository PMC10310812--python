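"""Marker panel, primer scheme, and sample sheet: the contract between the
wet-lab design and every computational stage.

A simplified one-step amplicon library is built from two primer sets: the
1st set carries target-specific primers extended with the R1/R2 sequencing
anchor tails, and the 2nd set carries the flow-cell binding regions (P5/P7),
8-nt sample indexes, and the same anchor tails. A fully extended library
molecule therefore exceeds its target amplicon by a fixed extension (135 bp
by default), while products amplified by the 1st primer set alone exceed it
only by the two tail lengths — the size arithmetic exposed here as
:func:`expected_library_size` and :func:`expected_incomplete_size`.

The panel is stored as one human-editable YAML file (scheme + markers) plus
a TSV sample sheet, because breeders swap target primers far more often
than they touch the outer library chemistry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import (
    AmbiguousPrimerError,
    DuplicateIndexPairError,
    DuplicateMarkerError,
    MalformedSequenceError,
    PanelValidationError,
    ThresholdError,
)
from .seq import is_dna

# Anchor-tail and flow-cell sequences of the default Illumina-style scheme.
DEFAULT_R1_TAIL = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"  # 33 nt forward anchor
DEFAULT_R2_TAIL = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"  # 34 nt reverse anchor
DEFAULT_P5 = "AATGATACGGCGACCACCGAGATCTACAC"
DEFAULT_P7 = "CAAGCAGAAGACGGCATACGAGAT"

MARKER_CLASSES = ("SSR", "SNP", "indel", "dominant")

SAMPLE_SHEET_COLUMNS = ("sample_id", "i5", "i7", "ploidy", "replicate_id")


@dataclass
class PrimerScheme:
    """Outer library architecture: anchor tails, flow-cell regions, indexes.

    ``extension_length`` is the total size added to a target amplicon by the
    outer structure (tails + indexes + flow-cell sites) and is taken as a
    single given number rather than recomputed from the part lengths, since
    the parts overlap the 2nd primers.
    """

    r1_tail: str = DEFAULT_R1_TAIL
    r2_tail: str = DEFAULT_R2_TAIL
    p5_region: str = DEFAULT_P5
    p7_region: str = DEFAULT_P7
    index_length: int = 8
    extension_length: int = 135

    def __post_init__(self) -> None:
        for name in ("r1_tail", "r2_tail", "p5_region", "p7_region"):
            seq = getattr(self, name)
            if not is_dna(seq):
                raise MalformedSequenceError(f"scheme.{name}: not a DNA string: {seq!r}")
        if self.index_length < 1:
            raise PanelValidationError(f"index_length must be >= 1, got {self.index_length}")


@dataclass
class MarkerDef:
    """One target marker: primers, expected size, variant model, MAS rule.

    ``target_alleles`` are bp lengths for SSR/indel markers, haplotype names
    for SNP markers, and the single token "present" for dominant markers.
    ``carrier_threshold`` is the target-allele frequency above which (strictly)
    an individual is judged a carrier; it is per-marker because stutter-prone
    loci need a lower criterion.
    """

    name: str
    marker_class: str
    fwd_primer: str
    rev_primer: str
    ref_amplicon_length: int
    trait: str = ""
    repeat_unit: int | None = None
    variant_offsets: list[int] = field(default_factory=list)
    target_alleles: list = field(default_factory=list)
    carrier_threshold: float | None = None
    carrier_label: str = "carrier"
    noncarrier_label: str = "non-carrier"

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise PanelValidationError(
                f"marker {self.name!r}: class {self.marker_class!r} not one of {MARKER_CLASSES}"
            )
        for fname in ("fwd_primer", "rev_primer"):
            seq = getattr(self, fname)
            if not is_dna(seq):
                raise MalformedSequenceError(f"marker {self.name!r}: {fname} not DNA: {seq!r}")
        if self.fwd_primer == self.rev_primer:
            raise PanelValidationError(f"marker {self.name!r}: fwd and rev primers identical")
        if self.ref_amplicon_length < len(self.fwd_primer) + len(self.rev_primer):
            raise PanelValidationError(
                f"marker {self.name!r}: ref_amplicon_length {self.ref_amplicon_length} "
                f"shorter than combined primers"
            )
        if self.marker_class == "SSR":
            if self.repeat_unit is None or self.repeat_unit < 1:
                raise PanelValidationError(
                    f"marker {self.name!r}: SSR markers need repeat_unit >= 1"
                )
        if self.marker_class == "SNP" and not self.variant_offsets:
            raise PanelValidationError(
                f"marker {self.name!r}: SNP markers need at least one variant offset"
            )
        if self.carrier_threshold is not None and not 0.0 < self.carrier_threshold < 1.0:
            raise ThresholdError(
                f"marker {self.name!r}: carrier_threshold {self.carrier_threshold} "
                f"not strictly between 0 and 1"
            )


@dataclass
class SampleRecord:
    """One pooled sample: unique dual-index pair plus ploidy."""

    sample_id: str
    i5_index: str
    i7_index: str
    ploidy: int = 2
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        for fname in ("i5_index", "i7_index"):
            seq = getattr(self, fname)
            if not is_dna(seq):
                raise MalformedSequenceError(f"sample {self.sample_id!r}: {fname} not DNA: {seq!r}")
        if not 1 <= self.ploidy <= 8:
            raise PanelValidationError(
                f"sample {self.sample_id!r}: ploidy {self.ploidy} outside supported 1..8"
            )


@dataclass
class MarkerPanel:
    """Primer scheme + marker definitions + sample sheet, jointly validated."""

    scheme: PrimerScheme = field(default_factory=PrimerScheme)
    markers: list[MarkerDef] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_names: set[str] = set()
        for m in self.markers:
            if m.name in seen_names:
                raise DuplicateMarkerError(f"duplicate marker name {m.name!r}")
            seen_names.add(m.name)
        # Prefix-nested forward primers would misassign reads silently.
        for a in self.markers:
            for b in self.markers:
                if a.name != b.name and b.fwd_primer.startswith(a.fwd_primer):
                    raise AmbiguousPrimerError(
                        f"fwd primer of {a.name!r} is a prefix of {b.name!r}'s"
                    )
        seen_pairs: set[tuple[str, str]] = set()
        for s in self.samples:
            if len(s.i5_index) != self.scheme.index_length or len(s.i7_index) != self.scheme.index_length:
                raise PanelValidationError(
                    f"sample {s.sample_id!r}: index length != scheme index_length "
                    f"{self.scheme.index_length}"
                )
            pair = (s.i5_index, s.i7_index)
            if pair in seen_pairs:
                raise DuplicateIndexPairError(
                    f"sample {s.sample_id!r}: index pair {pair} already used"
                )
            seen_pairs.add(pair)

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"no marker named {name!r}")

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample named {sample_id!r}")


def expected_library_size(marker: MarkerDef, scheme: PrimerScheme) -> int:
    """Size (bp) of the fully extended library molecule for ``marker``.

    Target amplicon plus the fixed extension contributed by tails, indexes,
    and flow-cell binding sites: the 242–271 bp band a successful one-step
    reaction produces for 107–136 bp target amplicons.
    """
    return marker.ref_amplicon_length + scheme.extension_length


def expected_incomplete_size(marker: MarkerDef, scheme: PrimerScheme) -> int:
    """Size (bp) of an incomplete (1st-primer-only) product for ``marker``.

    These products carry the two anchor tails but no flow-cell or index
    sequences, so they cannot be sequenced; they show up as the short
    background band on a gel (174 bp upward for the panels considered here).
    """
    return marker.ref_amplicon_length + len(scheme.r1_tail) + len(scheme.r2_tail)


# ---------------------------------------------------------------------------
# Config I/O


def _marker_to_dict(m: MarkerDef) -> dict:
    d: dict = {
        "name": m.name,
        "trait": m.trait,
        "marker_class": m.marker_class,
        "fwd_primer": m.fwd_primer,
        "rev_primer": m.rev_primer,
        "ref_amplicon_length": m.ref_amplicon_length,
    }
    if m.repeat_unit is not None:
        d["repeat_unit"] = m.repeat_unit
    if m.variant_offsets:
        d["variant_offsets"] = list(m.variant_offsets)
    if m.target_alleles:
        d["target_alleles"] = list(m.target_alleles)
    if m.carrier_threshold is not None:
        d["carrier_threshold"] = m.carrier_threshold
        d["carrier_label"] = m.carrier_label
        d["noncarrier_label"] = m.noncarrier_label
    return d


def write_sample_sheet(samples: list[SampleRecord], path: str | Path) -> None:
    """Write the TSV sample sheet (header: sample_id, i5, i7, ploidy, replicate_id)."""
    buf = io.StringIO()
    buf.write("\t".join(SAMPLE_SHEET_COLUMNS) + "\n")
    for s in samples:
        rep = s.replicate_id if s.replicate_id is not None else ""
        buf.write(f"{s.sample_id}\t{s.i5_index}\t{s.i7_index}\t{s.ploidy}\t{rep}\n")
    Path(path).write_text(buf.getvalue())


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    if tuple(header) != SAMPLE_SHEET_COLUMNS:
        raise PanelValidationError(
            f"sample sheet {path}: header {header} != expected {list(SAMPLE_SHEET_COLUMNS)}"
        )
    samples = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise PanelValidationError(f"sample sheet {path}: malformed row {line!r}")
        sid, i5, i7, ploidy, rep = fields
        samples.append(
            SampleRecord(
                sample_id=sid,
                i5_index=i5,
                i7_index=i7,
                ploidy=int(ploidy),
                replicate_id=rep or None,
            )
        )
    return samples


def write_panel(panel: MarkerPanel, path: str | Path, sheet_path: str | Path | None = None) -> None:
    """Write a panel as YAML plus a TSV sample sheet next to it.

    The emitted files are deterministic (stable key order) so that
    write → load → write round-trips bit-identically.
    """
    path = Path(path)
    if sheet_path is None:
        sheet_path = path.with_suffix(".samples.tsv")
    sheet_path = Path(sheet_path)
    doc = {
        "scheme": {
            "r1_tail": panel.scheme.r1_tail,
            "r2_tail": panel.scheme.r2_tail,
            "p5_region": panel.scheme.p5_region,
            "p7_region": panel.scheme.p7_region,
            "index_length": panel.scheme.index_length,
            "extension_length": panel.scheme.extension_length,
        },
        "markers": [_marker_to_dict(m) for m in panel.markers],
        "sample_sheet": sheet_path.name,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    write_sample_sheet(panel.samples, sheet_path)


def load_panel(path: str | Path) -> MarkerPanel:
    """Load and validate a panel config (YAML + referenced TSV sample sheet).

    Samples may alternatively be inlined under a ``samples`` key; an absent
    sample section yields a valid panel with an empty sample list.
    """
    path = Path(path)
    if not path.exists():
        raise PanelValidationError(f"panel config not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "markers" not in doc:
        raise PanelValidationError(f"panel config {path}: missing 'markers' section")
    scheme = PrimerScheme(**(doc.get("scheme") or {}))
    markers = [MarkerDef(**m) for m in doc["markers"]]
    if "sample_sheet" in doc and doc["sample_sheet"]:
        sheet = path.parent / doc["sample_sheet"]
        if not sheet.exists():
            raise PanelValidationError(f"sample sheet not found: {sheet}")
        samples = read_sample_sheet(sheet)
    elif "samples" in doc and doc["samples"]:
        samples = [SampleRecord(**s) for s in doc["samples"]]
    else:
        samples = []
    return MarkerPanel(scheme=scheme, markers=markers, samples=samples)
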