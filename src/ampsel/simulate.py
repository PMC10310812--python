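"""Synthetic paired-end read generator emulating a simplified one-step
amplicon library.

The generator produces, per (sample, marker), a configured number of read
pairs drawn from three product classes:

* **on-target** — fully extended molecules: the primer-inclusive target
  amplicon flanked by anchor tails, dual 8-nt indexes, and flow-cell
  regions. Read 1 starts at the amplicon and reads through into the
  reverse-anchor adapter; read 2 mirrors it from the other strand, so
  adapter trimming and overlap merging are both exercised.
* **incomplete** — 1st-primer-only products (amplicon plus the two anchor
  tails, no indexes or flow-cell sites). Real instruments cannot sequence
  these; they are emitted with blank (all-N) index fields so that they
  stress the demultiplexer the way untrackable background would.
* **dimer** — primer-dimer artifacts: the two target primers joined with no
  insert, always shorter than 80 bp, carrying valid sample indexes. The
  80-bp length filter downstream is what removes them.

For SSR markers a read's allele length may slip downward by whole repeat
units (classic PCR stutter). The slippage model is geometric: a read
stutters at all with probability ``stutter_prob`` and then loses ``k``
units with P(k) ∝ stutter_continue^(k-1); a single-unit upward slip occurs
with ``plus_one_prob``. Geometric decay is the standard slippage model and
reproduces the observed "stutter ladder" below long repeat alleles.

Sequencing error is uniform per-base substitution; bases carrying a
simulated error are written at Q15 against a Q30 background so that
quality trimming has something real to act on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AmpselError
from .panel import MarkerDef, MarkerPanel
from .seq import revcomp

READ_CLASSES = ("on_target", "incomplete", "dimer", "hopped")

_Q30 = "?"  # Phred+33
_Q15 = "0"


@dataclass
class TruthGenotype:
    """True allelic constitution of one (sample, marker).

    ``allele_copies`` pairs an allele key with its dosage; dosages must sum
    to the sample's ploidy. Allele keys are bp lengths for SSR/indel
    markers, full insert sequences for SNP markers, and "present" for
    dominant markers.
    """

    sample_id: str
    marker: str
    allele_copies: list[tuple[object, int]]


@dataclass
class SimConfig:
    """Tunable noise and depth parameters of the simulated library."""

    mean_depth_per_marker: int = 1000
    stutter_prob: float = 0.1
    stutter_continue: float = 0.4
    plus_one_prob: float = 0.02
    seq_error_rate: float = 0.003
    incomplete_frac: float = 0.05
    dimer_frac: float = 0.05
    hop_rate: float = 0.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stutter_prob",
            "stutter_continue",
            "plus_one_prob",
            "seq_error_rate",
            "incomplete_frac",
            "dimer_frac",
            "hop_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AmpselError(f"SimConfig.{name}={v} outside [0, 1]")
        if self.stutter_prob + self.plus_one_prob > 1.0:
            raise AmpselError("stutter_prob + plus_one_prob exceeds 1")
        if self.incomplete_frac + self.dimer_frac > 1.0:
            raise AmpselError("incomplete_frac + dimer_frac exceeds 1")
        if self.mean_depth_per_marker < 0:
            raise AmpselError("mean_depth_per_marker must be >= 0")


@dataclass
class SimResult:
    r1_path: Path
    r2_path: Path
    truth_path: Path
    class_counts: dict = field(default_factory=dict)


def sample_stutter(
    length: int,
    unit: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    min_length: int = 0,
) -> int:
    """Draw one stuttered allele length from the geometric slippage mixture.

    With probability ``plus_one_prob`` the product gains one repeat unit;
    otherwise with probability ``stutter_prob`` it loses ``k >= 1`` units,
    where ``k - 1`` continues geometrically with ``stutter_continue``. The
    result never drops below ``min_length`` (the combined primer length).
    """
    if unit < 1:
        raise AmpselError(f"repeat unit must be >= 1, got {unit}")
    u = rng.random()
    if u < cfg.plus_one_prob:
        return length + unit
    if u < cfg.plus_one_prob + cfg.stutter_prob:
        k = int(rng.geometric(1.0 - cfg.stutter_continue)) if cfg.stutter_continue > 0 else 1
        out = length - k * unit
        return max(out, min_length, length - ((length - min_length) // unit) * unit)
    return length


def _marker_rng(seed: int, marker_name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(marker_name.encode())])


def _ssr_motif(unit: int) -> str:
    # Deterministic repeat motif of the requested unit length.
    base = "CTAG"
    return (base * ((unit // 4) + 1))[:unit]


def _marker_filler(marker: MarkerDef, seed: int, max_len: int) -> str:
    """Fixed filler sequence between the primers for non-SSR markers."""
    rng = _marker_rng(seed, marker.name)
    return "".join(rng.choice(list("ACGT"), size=max_len))


class _InsertBuilder:
    """Builds primer-inclusive amplicon sequences for a marker's alleles."""

    def __init__(self, marker: MarkerDef, seed: int):
        self.marker = marker
        self.fwd = marker.fwd_primer
        self.rev_rc = revcomp(marker.rev_primer)
        self.min_len = len(self.fwd) + len(self.rev_rc)
        if marker.marker_class == "SSR":
            self._filler = _ssr_motif(marker.repeat_unit) * 200
        else:
            self._filler = _marker_filler(marker, seed, 400)

    def insert(self, allele: object) -> str:
        if isinstance(allele, str) and allele not in ("present",):
            return allele  # SNP haplotype: full insert sequence supplied
        length = self.marker.ref_amplicon_length if allele == "present" else int(allele)
        if length < self.min_len:
            raise AmpselError(
                f"marker {self.marker.name!r}: allele {allele} shorter than combined primers"
            )
        fill = self._filler[: length - self.min_len]
        return self.fwd + fill + self.rev_rc

    def dimer(self) -> str:
        return (self.fwd + self.rev_rc)[:79]


def _apply_errors(seq: str, cfg: SimConfig, rng: np.random.Generator) -> tuple[str, str]:
    """Substitute bases at rate seq_error_rate; return (seq, quality)."""
    n = len(seq)
    qual = _Q30 * n
    if cfg.seq_error_rate <= 0 or n == 0:
        return seq, qual
    n_err = rng.binomial(n, cfg.seq_error_rate)
    if n_err == 0:
        return seq, qual
    pos = rng.choice(n, size=n_err, replace=False)
    s = list(seq)
    q = list(qual)
    for p in pos:
        orig = s[p]
        choices = [b for b in "ACGT" if b != orig]
        s[p] = choices[rng.integers(3)]
        q[p] = _Q15
    return "".join(s), "".join(q)


def simulate_library(
    panel: MarkerPanel,
    truth: list[TruthGenotype],
    cfg: SimConfig,
    out_dir: str | Path,
) -> SimResult:
    """Simulate paired FASTQ files plus a per-read truth table.

    Deterministic given (panel, truth order, cfg, cfg.seed): identical
    inputs produce byte-identical output files. Per (sample, marker) the
    configured depth is split exactly into dimer / incomplete / on-target
    counts (rounded fractions), and each on-target read's allele is drawn
    from the truth dosages.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    sample_by_id = {s.sample_id: s for s in panel.samples}
    marker_by_name = {m.name: m for m in panel.markers}
    builders = {m.name: _InsertBuilder(m, cfg.seed) for m in panel.markers}

    for t in truth:
        if t.sample_id not in sample_by_id:
            raise AmpselError(f"truth references unknown sample {t.sample_id!r}")
        if t.marker not in marker_by_name:
            raise AmpselError(f"truth references unknown marker {t.marker!r}")
        sample = sample_by_id[t.sample_id]
        total = sum(c for _, c in t.allele_copies)
        if total != sample.ploidy:
            raise AmpselError(
                f"truth {t.sample_id}/{t.marker}: dosages sum to {total}, ploidy {sample.ploidy}"
            )

    r1_path = out_dir / "R1.fastq"
    r2_path = out_dir / "R2.fastq"
    truth_path = out_dir / "truth.tsv"
    class_counts = {c: 0 for c in READ_CLASSES}
    other_i7 = {
        s.sample_id: [o.i7_index for o in panel.samples if o.sample_id != s.sample_id]
        for s in panel.samples
    }
    L = cfg.read_length
    serial = 0

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, open(truth_path, "w") as ft:
        ft.write("read_id\tsample_id\tmarker\tclass\ttrue_allele\n")

        def emit(rid, header_idx, r1_seq, r2_seq, sample_id, marker, cls, allele):
            s1, q1 = _apply_errors(r1_seq, cfg, rng)
            s2, q2 = _apply_errors(r2_seq, cfg, rng)
            f1.write(f"@{rid} 1:N:0:{header_idx}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid} 2:N:0:{header_idx}\n{s2}\n+\n{q2}\n")
            ft.write(f"{rid}\t{sample_id}\t{marker}\t{cls}\t{allele}\n")
            class_counts[cls] += 1

        scheme = panel.scheme
        rc_r1_tail = revcomp(scheme.r1_tail)
        rc_r2_tail = revcomp(scheme.r2_tail)
        rc_p5 = revcomp(scheme.p5_region)
        rc_p7 = revcomp(scheme.p7_region)
        rc_i5 = {s.sample_id: revcomp(s.i5_index) for s in panel.samples}
        rc_i7_all = {s.i7_index: revcomp(s.i7_index) for s in panel.samples}

        for t in truth:
            sample = sample_by_id[t.sample_id]
            marker = marker_by_name[t.marker]
            build = builders[t.marker]
            n_total = cfg.mean_depth_per_marker
            n_dim = int(round(cfg.dimer_frac * n_total))
            n_inc = int(round(cfg.incomplete_frac * n_total))
            n_on = n_total - n_dim - n_inc

            # --- on-target reads, allele drawn by dosage ----------------
            alleles = [a for a, _ in t.allele_copies]
            probs = np.array([c for _, c in t.allele_copies], dtype=float)
            probs /= probs.sum()
            per_allele = rng.multinomial(n_on, probs)
            for allele, n_reads in zip(alleles, per_allele):
                for _ in range(n_reads):
                    serial += 1
                    obs_allele = allele
                    if (
                        marker.marker_class == "SSR"
                        and (cfg.stutter_prob > 0 or cfg.plus_one_prob > 0)
                    ):
                        obs_allele = sample_stutter(
                            int(allele), marker.repeat_unit, cfg, rng, build.min_len
                        )
                    insert = build.insert(obs_allele)
                    i5, i7 = sample.i5_index, sample.i7_index
                    cls = "on_target"
                    if cfg.hop_rate > 0 and other_i7[sample.sample_id]:
                        if rng.random() < cfg.hop_rate:
                            i7 = other_i7[sample.sample_id][
                                rng.integers(len(other_i7[sample.sample_id]))
                            ]
                            cls = "hopped"
                    r1 = (insert + rc_r2_tail + rc_i7_all.get(i7, revcomp(i7)) + rc_p7)[:L]
                    r2 = (revcomp(insert) + rc_r1_tail + rc_i5[sample.sample_id] + rc_p5)[:L]
                    rid = f"sim:{t.sample_id}:{t.marker}:{cls}:{serial:07d}"
                    truth_allele = obs_allele if not isinstance(obs_allele, str) else "haplotype"
                    emit(rid, f"{i5}+{i7}", r1, r2, t.sample_id, t.marker, cls, truth_allele)

            # --- incomplete (tail-only) products ------------------------
            blank = "N" * scheme.index_length
            for _ in range(n_inc):
                serial += 1
                allele = alleles[rng.integers(len(alleles))]
                mol = scheme.r1_tail + build.insert(allele) + rc_r2_tail
                rid = f"sim:{t.sample_id}:{t.marker}:incomplete:{serial:07d}"
                emit(
                    rid, f"{blank}+{blank}", mol[:L], revcomp(mol)[:L],
                    t.sample_id, t.marker, "incomplete", "NA",
                )

            # --- primer dimers ------------------------------------------
            dim = build.dimer()
            for _ in range(n_dim):
                serial += 1
                r1 = (dim + rc_r2_tail + rc_i7_all[sample.i7_index] + rc_p7)[:L]
                r2 = (revcomp(dim) + rc_r1_tail + rc_i5[sample.sample_id] + rc_p5)[:L]
                rid = f"sim:{t.sample_id}:{t.marker}:dimer:{serial:07d}"
                emit(
                    rid, f"{sample.i5_index}+{sample.i7_index}", r1, r2,
                    t.sample_id, t.marker, "dimer", "NA",
                )

    return SimResult(r1_path, r2_path, truth_path, class_counts)
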