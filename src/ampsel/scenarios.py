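"""Canned simulation studies: recover allele-frequency anchors end to end.

Each scenario builds a one-marker panel, simulates a library under a
stated genotype composition and noise model, pushes the reads through the
full pipeline (demux → trim/merge → assign/count → top alleles), and
summarises the recovered frequencies. They serve as self-contained
calibration experiments for the frequency anchors genotyping relies on:
homozygous diploids near 0.8, heterozygous diploids near 0.4, a balanced
triploid's third allele above 0.2, and a duplex/simplex triploid's first
allele near 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .assign_count import AlleleTable, MarkerAssigner, top_alleles
from .panel import MarkerDef, MarkerPanel, PrimerScheme, SampleRecord
from .readprep import prep_reads
from .simulate import SimConfig, TruthGenotype, simulate_library

_FWD = "ATCGGATTACCAGGTTCACA"
_REV = "TGGTCAACCTTGATCGTACC"

_INDEX_ALPHA = "ACGT"


def _index(i: int, which: int) -> str:
    # deterministic unique 8-mers: base-4 encoding of (i, which)
    n = i * 2 + which
    return "".join(_INDEX_ALPHA[(n >> (2 * k)) & 3] for k in range(8))


def ssr_panel(n_samples: int, ploidy: int = 2, repeat_unit: int = 3, ref_len: int = 127) -> MarkerPanel:
    """One-SSR panel with ``n_samples`` samples of the given ploidy."""
    marker = MarkerDef(
        name="SSR1",
        marker_class="SSR",
        fwd_primer=_FWD,
        rev_primer=_REV,
        ref_amplicon_length=ref_len,
        repeat_unit=repeat_unit,
    )
    samples = [
        SampleRecord(f"s{i:03d}", _index(i, 0), _index(i, 1), ploidy=ploidy)
        for i in range(n_samples)
    ]
    return MarkerPanel(scheme=PrimerScheme(), markers=[marker], samples=samples)


@dataclass
class ScenarioResult:
    per_sample: list  # TopAlleles per sample
    mean_freq1: float
    mean_freq3: float | None
    n_samples: int


def run_frequency_scenario(
    genotype: list[tuple[int, int]],
    n_samples: int,
    ploidy: int,
    depth: int,
    stutter_prob: float,
    stutter_continue: float,
    seq_error_rate: float,
    seed: int,
    repeat_unit: int = 3,
    freq1_allele: int | None = None,
    work_dir: str | Path | None = None,
) -> ScenarioResult:
    """Simulate ``n_samples`` identical genotypes and recover frequencies.

    ``genotype`` is a list of (allele length, copies) summing to ``ploidy``.
    ``freq1_allele`` optionally pins which allele's frequency is reported
    as Freq1 (otherwise the most common observed allele is used).
    Returns per-sample top alleles plus the across-sample mean Freq1 and,
    when at least three alleles are observed, mean Freq3.
    """
    import tempfile

    panel = ssr_panel(n_samples, ploidy=ploidy, repeat_unit=repeat_unit)
    truth = [
        TruthGenotype(s.sample_id, "SSR1", list(genotype)) for s in panel.samples
    ]
    cfg = SimConfig(
        mean_depth_per_marker=depth,
        stutter_prob=stutter_prob,
        stutter_continue=stutter_continue,
        seq_error_rate=seq_error_rate,
        incomplete_frac=0.05,
        dimer_frac=0.05,
        seed=seed,
    )
    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    out = Path(ctx.name) if ctx else Path(work_dir)
    try:
        res = simulate_library(panel, truth, cfg, out)
        merged, _stats = prep_reads(res.r1_path, res.r2_path, panel)
        assigner = MarkerAssigner(panel)
        tops = []
        f1, f3 = [], []
        for s in panel.samples:
            table = AlleleTable(sample_id=s.sample_id, marker="SSR1")
            for r in merged[s.sample_id]:
                if assigner.assign(r.sequence) == "SSR1":
                    table.add(r.length)
            top = top_alleles(table)
            tops.append(top)
            if top.no_data:
                continue
            if freq1_allele is not None:
                freq_of = {a: f for a, _, f in top.entries}
                f1.append(freq_of.get(freq1_allele, 0.0))
            else:
                f1.append(top.entries[0][2])
            if len(top.entries) >= 3:
                f3.append(top.entries[2][2])
    finally:
        if ctx:
            ctx.cleanup()
    return ScenarioResult(
        per_sample=tops,
        mean_freq1=sum(f1) / len(f1) if f1 else 0.0,
        mean_freq3=sum(f3) / len(f3) if f3 else None,
        n_samples=n_samples,
    )
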