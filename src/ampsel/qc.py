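"""Library- and replicate-level diagnostics.

Two views matter in practice: how the sequencing budget is spent (the
share of reads each marker captures, the on-target fraction, and the
spread between the best- and worst-amplifying marker), and whether the
first-allele frequency — the single number genotypes hinge on — is
repeatable between replicate runs of the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as _scipy_stats

from .assign_count import AlleleTable, TopAlleles
from .errors import AmpselError

MIN_REPEATABILITY_SAMPLES = 3


@dataclass
class MarkerProportions:
    scope: str  # sample_id or "cohort"
    proportions: dict = field(default_factory=dict)  # marker -> share of total reads
    on_target_sum: float = 0.0
    unassigned_fraction: float = 0.0
    bias: float = 0.0  # max - min spread of per-marker proportions
    n_samples: int = 0
    excluded_samples: list = field(default_factory=list)


@dataclass
class RepeatabilityResult:
    marker: str
    n_samples: int
    correlation: float | None
    mean_freq1: tuple[float, float] | None
    excluded: int = 0
    reason: str | None = None


def marker_read_proportions(
    tables: list[AlleleTable], scope: str = "cohort"
) -> MarkerProportions:
    """Per-marker share of total sample reads, per sample or cohort-averaged.

    Cohort proportions are the mean of per-sample proportions (each sample
    weighted equally, not read-weighted). Samples with zero total reads
    are excluded and listed. ``bias`` is the max-minus-min spread of the
    per-marker proportions, a scalar summary of amplification imbalance.
    """
    by_sample: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for t in tables:
        by_sample.setdefault(t.sample_id, {})[t.marker] = t.total_marker_reads
        totals[t.sample_id] = max(totals.get(t.sample_id, 0), t.total_sample_reads)

    if scope != "cohort":
        by_sample = {scope: by_sample.get(scope, {})}

    markers = sorted({m for d in by_sample.values() for m in d})
    excluded = [sid for sid, tot in totals.items() if tot == 0 and sid in by_sample]
    usable = [sid for sid in by_sample if totals.get(sid, 0) > 0]
    result = MarkerProportions(scope=scope, n_samples=len(usable), excluded_samples=sorted(excluded))
    if not usable:
        return result
    for m in markers:
        result.proportions[m] = sum(
            by_sample[sid].get(m, 0) / totals[sid] for sid in usable
        ) / len(usable)
    result.on_target_sum = sum(result.proportions.values())
    result.unassigned_fraction = 1.0 - result.on_target_sum
    if result.proportions:
        vals = list(result.proportions.values())
        result.bias = max(vals) - min(vals)
    return result


def repeatability(
    run_a: list[TopAlleles],
    run_b: list[TopAlleles],
    marker: str,
    method: str = "pearson",
) -> RepeatabilityResult:
    """Correlation of first-allele frequency between two replicate runs.

    Computed over samples present with data in both runs; fewer than three
    shared samples yields a no-report with the reason. ``method`` is
    "pearson" (default) or "spearman". Symmetric in the two runs.
    """
    if method not in ("pearson", "spearman"):
        raise AmpselError(f"unknown correlation method {method!r}")

    def freq1_map(run):
        out = {}
        for t in run:
            if t.marker == marker and not t.no_data and t.entries:
                out[t.sample_id] = t.entries[0][2]
        return out

    fa, fb = freq1_map(run_a), freq1_map(run_b)
    shared = sorted(set(fa) & set(fb))
    excluded = len(set(fa) ^ set(fb))
    if len(shared) < MIN_REPEATABILITY_SAMPLES:
        return RepeatabilityResult(
            marker=marker,
            n_samples=len(shared),
            correlation=None,
            mean_freq1=None,
            excluded=excluded,
            reason=f"only {len(shared)} shared samples (need {MIN_REPEATABILITY_SAMPLES})",
        )
    xs = [fa[s] for s in shared]
    ys = [fb[s] for s in shared]
    if method == "pearson":
        r = float(_scipy_stats.pearsonr(xs, ys).statistic)
    else:
        r = float(_scipy_stats.spearmanr(xs, ys).statistic)
    return RepeatabilityResult(
        marker=marker,
        n_samples=len(shared),
        correlation=r,
        mean_freq1=(sum(xs) / len(xs), sum(ys) / len(ys)),
        excluded=excluded,
    )
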