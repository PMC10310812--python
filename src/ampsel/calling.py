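"""Ploidy-aware genotype calling and target-allele-frequency selection.

Genotypes are called from allele frequencies alone. In diploids a
homozygote shows a first-allele frequency around 0.8 and a heterozygote
around 0.4 (the rest of the mass sits in stutter and background), which is
what the ``homo_threshold`` default of 0.65 separates. In polyploids each
true allele's frequency approaches dosage/ploidy, so a balanced triploid
shows three alleles above 0.2 while diploids keep their third allele below
a few percent; dosage within a call is apportioned by largest remainder.

Stutter attribution runs before any thresholding: an allele exactly one
repeat unit below a more frequent allele, with a frequency ratio at most
``stutter_ratio``, is folded into that allele as a slippage artifact.
Cases where a stutter band rivals or exceeds its parent cannot be resolved
automatically and are flagged ("stutter-ambiguous"), never silently
inverted — they are exactly the cases a human resolves by inspecting the
electropherogram.

Marker-assisted selection skips genotyping entirely: an individual carries
a target allele iff that allele's frequency strictly exceeds the marker's
carrier threshold, and is selected iff it carries the target at every
required marker.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import AmpselError
from .assign_count import AlleleTable, TopAlleles
from .panel import MarkerDef


@dataclass
class CallingParams:
    """Frequency thresholds for genotype calling; all judgement-based and
    configurable.

    presence_threshold: minimum frequency for an allele to be treated as
        real rather than noise/stutter remnant (default 0.10).
    homo_threshold: first-allele frequency above which a lone candidate is
        a confident homozygote in a diploid (default 0.65, between the
        ~0.4 heterozygous and ~0.8 homozygous anchors).
    het_floor: minimum second-allele frequency for heterozygosity (0.20).
    stutter_ratio: maximum frequency ratio child/parent attributable to
        slippage when the child sits one repeat unit below (0.5).
    min_marker_reads: below this depth calls are flagged "low-depth" but
        still attempted (50).
    """

    presence_threshold: float = 0.10
    homo_threshold: float = 0.65
    het_floor: float = 0.20
    stutter_ratio: float = 0.5
    min_marker_reads: int = 50

    def __post_init__(self) -> None:
        for name in ("presence_threshold", "homo_threshold", "het_floor", "stutter_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise AmpselError(f"CallingParams.{name}={v} outside (0, 1)")
        if self.min_marker_reads < 1:
            raise AmpselError("min_marker_reads must be >= 1")


@dataclass
class GenotypeCall:
    sample_id: str
    marker: str
    alleles_with_dosage: list[tuple[object, int]] = field(default_factory=list)
    ploidy: int = 2
    flags: set = field(default_factory=set)

    @property
    def rendering(self) -> str:
        """Deterministic "a/b" / "a/a/b" string, alleles ascending."""
        if not self.alleles_with_dosage:
            return "no-call"
        expanded = []
        for allele, dosage in self.alleles_with_dosage:
            expanded.extend([allele] * dosage)
        key = (lambda a: (0, a, "") if isinstance(a, int) else (1, 0, str(a)))
        return "/".join(str(a) for a in sorted(expanded, key=key))


@dataclass
class MASDecision:
    sample_id: str
    marker: str
    target_allele: object
    target_frequency: float
    carries: bool
    label: str
    flags: set = field(default_factory=set)


@dataclass
class SelectionReport:
    decisions: dict = field(default_factory=dict)  # sample_id -> list[MASDecision]
    selected: dict = field(default_factory=dict)  # sample_id -> bool

    def selected_samples(self) -> list[str]:
        return sorted(sid for sid, ok in self.selected.items() if ok)


# ---------------------------------------------------------------------------
# Stutter attribution and candidate extraction


def _fold_stutter(
    entries: list[tuple[object, int, float]], repeat_unit: int | None, stutter_ratio: float
) -> tuple[list[tuple[object, float]], set]:
    """Fold single-step stutter children into their parent alleles.

    An entry exactly one repeat unit below a larger-frequency entry, with a
    frequency ratio <= ``stutter_ratio``, has its mass added to the parent.
    Folding is one-directional (shorter into longer) and single-step only.
    Returns (allele, frequency) pairs sorted by frequency descending, plus
    flags raised along the way.
    """
    flags: set = set()
    freqs = {a: f for a, _, f in entries}
    if repeat_unit:
        for allele, _, _f in sorted(entries, key=lambda e: -e[2]):
            if not isinstance(allele, int) or allele not in freqs:
                continue
            parent = allele + repeat_unit
            if parent in freqs and freqs[parent] > freqs[allele] > 0.0:
                if freqs[allele] / freqs[parent] <= stutter_ratio:
                    freqs[parent] += freqs.pop(allele)
                else:
                    # plausible stutter too strong to attribute automatically
                    flags.add("stutter-ambiguous")
    merged = sorted(freqs.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return merged, flags


def _candidates(
    top: TopAlleles, marker: MarkerDef, params: CallingParams
) -> tuple[list[tuple[object, float]], set]:
    folded, flags = _fold_stutter(
        top.entries,
        marker.repeat_unit if marker.marker_class == "SSR" else None,
        params.stutter_ratio,
    )
    kept = [(a, f) for a, f in folded if f >= params.presence_threshold]
    return kept, flags


# ---------------------------------------------------------------------------
# Dosage apportionment


def largest_remainder_dosage(freqs: list[float], ploidy: int) -> list[int]:
    """Apportion ``ploidy`` copies among alleles by largest remainder.

    Every allele receives at least one copy; quotas are freq_i * ploidy
    (frequencies renormalized by the caller); remaining copies go to the
    largest fractional remainders, ties toward the higher-frequency
    (earlier-listed) allele.
    """
    k = len(freqs)
    if k == 0:
        return []
    if k > ploidy:
        raise AmpselError(f"{k} alleles cannot share ploidy {ploidy}")
    total = sum(freqs)
    quotas = [f / total * ploidy for f in freqs]
    dosage = [max(1, int(q)) for q in quotas]

    # marginal |quota - dosage| cost of removing / adding one copy
    def shed_delta(i: int) -> float:
        return abs(quotas[i] - (dosage[i] - 1)) - abs(quotas[i] - dosage[i])

    def grant_delta(i: int) -> float:
        return abs(quotas[i] - (dosage[i] + 1)) - abs(quotas[i] - dosage[i])

    # shed over-allocation at minimum cost; on ties unload the
    # lower-frequency (later) allele, keeping the higher-frequency loaded
    while sum(dosage) > ploidy:
        idx = min(
            (i for i in range(k) if dosage[i] > 1),
            key=lambda i: (shed_delta(i), -i),
        )
        dosage[idx] -= 1
    # grant remaining copies at minimum cost; ties load the
    # higher-frequency (earlier) allele
    while sum(dosage) < ploidy:
        idx = min(range(k), key=lambda i: (grant_delta(i), i))
        dosage[idx] += 1
    return dosage


def exhaustive_dosage(freqs: list[float], ploidy: int) -> list[int]:
    """Brute-force oracle: minimize sum |freq_i * ploidy - d_i| over all
    dosage vectors with sum d = ploidy, d_i >= 1; ties toward loading the
    higher-frequency allele. Independent check for the apportionment above.
    """
    k = len(freqs)
    if k == 0:
        return []
    total = sum(freqs)
    quotas = [f / total * ploidy for f in freqs]
    best, best_cost = None, None
    for combo in itertools.product(range(1, ploidy + 1), repeat=k):
        if sum(combo) != ploidy:
            continue
        cost = sum(abs(q - d) for q, d in zip(quotas, combo))
        key = (cost, [-d for d in combo])
        if best is None or key < best_cost:
            best, best_cost = list(combo), key
    return best


# ---------------------------------------------------------------------------
# Genotype calling


def call_diploid(top: TopAlleles, marker: MarkerDef, params: CallingParams | None = None) -> GenotypeCall:
    """Diploid genotype from the top-allele frequencies.

    Two candidate alleles above the presence threshold (after stutter
    attribution) make a heterozygote; a lone candidate at or above
    ``homo_threshold`` a homozygote; anything else is called with the best
    supported interpretation and flagged "stutter-ambiguous".
    """
    params = params or CallingParams()
    call = GenotypeCall(sample_id=top.sample_id, marker=top.marker, ploidy=2)
    if top.no_data or not top.entries:
        call.flags.add("no-call")
        return call
    if top.total_marker_reads < params.min_marker_reads:
        call.flags.add("low-depth")
    kept, flags = _candidates(top, marker, params)
    call.flags |= flags
    if not kept:
        call.flags.add("no-call")
        return call
    if len(kept) == 2:
        call.alleles_with_dosage = [(kept[0][0], 1), (kept[1][0], 1)]
    elif len(kept) == 1:
        allele, f = kept[0]
        if f < params.homo_threshold:
            call.flags.add("stutter-ambiguous")
        call.alleles_with_dosage = [(allele, 2)]
    else:
        call.flags.add("stutter-ambiguous")
        call.alleles_with_dosage = [(kept[0][0], 1), (kept[1][0], 1)]
    return call


def call_polyploid(
    top: TopAlleles, ploidy: int, marker: MarkerDef, params: CallingParams | None = None
) -> GenotypeCall:
    """Genotype with allele dosage for ploidy >= 2.

    Alleles above the presence threshold (after stutter attribution) are
    retained, their frequencies renormalized, and the ploidy apportioned by
    largest remainder with every retained allele receiving at least one
    copy. More retained alleles than the ploidy can hold is flagged
    "over-allelic" and truncated to the most frequent.
    """
    params = params or CallingParams()
    if ploidy < 2:
        raise AmpselError(f"call_polyploid requires ploidy >= 2, got {ploidy}")
    call = GenotypeCall(sample_id=top.sample_id, marker=top.marker, ploidy=ploidy)
    if top.no_data or not top.entries:
        call.flags.add("no-call")
        return call
    if top.total_marker_reads < params.min_marker_reads:
        call.flags.add("low-depth")
    kept, flags = _candidates(top, marker, params)
    call.flags |= flags
    if not kept:
        call.flags.add("no-call")
        return call
    if len(kept) > ploidy:
        call.flags.add("over-allelic")
        kept = kept[:ploidy]
    freqs = [f for _, f in kept]
    dosage = largest_remainder_dosage(freqs, ploidy)
    call.alleles_with_dosage = [(a, d) for (a, _), d in zip(kept, dosage)]
    return call


# ---------------------------------------------------------------------------
# Marker-assisted selection


def evaluate_mas(
    table_or_top: AlleleTable | TopAlleles, marker: MarkerDef
) -> MASDecision:
    """Carrier judgement by target-allele frequency.

    The target frequency is the summed frequency of the marker's target
    alleles over the full allele table (several favorable alleles sum);
    carrier iff strictly greater than the marker's threshold. Dominant
    markers judge on the marker's share of the sample total instead.
    """
    if marker.carrier_threshold is None or not marker.target_alleles:
        raise AmpselError(f"marker {marker.name!r} has no MAS target/threshold configured")

    if isinstance(table_or_top, TopAlleles):
        sample_id = table_or_top.sample_id
        total = table_or_top.total_marker_reads
        counts = {a: c for a, c, _ in table_or_top.entries}
        sample_total = table_or_top.total_sample_reads
    else:
        sample_id = table_or_top.sample_id
        total = table_or_top.total_marker_reads
        counts = table_or_top.counts
        sample_total = table_or_top.total_sample_reads

    target_repr = (
        marker.target_alleles[0] if len(marker.target_alleles) == 1 else marker.target_alleles
    )
    if marker.marker_class == "dominant":
        if sample_total <= 0:
            freq = 0.0
        else:
            freq = total / sample_total
    elif total == 0:
        decision = MASDecision(
            sample_id=sample_id,
            marker=marker.name,
            target_allele=target_repr,
            target_frequency=0.0,
            carries=False,
            label=marker.noncarrier_label,
        )
        decision.flags.add("no-data")
        return decision
    else:
        freq = sum(counts.get(a, 0) for a in marker.target_alleles) / total

    carries = freq > marker.carrier_threshold
    return MASDecision(
        sample_id=sample_id,
        marker=marker.name,
        target_allele=target_repr,
        target_frequency=freq,
        carries=carries,
        label=marker.carrier_label if carries else marker.noncarrier_label,
    )


def select_individuals(
    decisions: list[MASDecision], required_markers: list[str]
) -> SelectionReport:
    """Cross-marker selection: keep samples carrying every required marker.

    Every sample must have a decision for every required marker; a missing
    decision is a hard error naming the gap (an empty requirement list
    vacuously selects everyone).
    """
    report = SelectionReport()
    for d in decisions:
        report.decisions.setdefault(d.sample_id, []).append(d)
    for sid, ds in sorted(report.decisions.items()):
        by_marker = {d.marker: d for d in ds}
        for m in required_markers:
            if m not in by_marker:
                raise AmpselError(f"sample {sid!r} has no MAS decision for marker {m!r}")
        report.selected[sid] = all(by_marker[m].carries for m in required_markers)
    return report
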