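"""Tabular report readers/writers.

The central interchange format is ``allele_table.tsv``, whose columns
mirror the familiar genotyping-report shape — total reads, marker reads,
then the four most common alleles with their frequencies rendered to two
decimals and "NA"-padded. A table in this shape can re-enter the pipeline
through :func:`read_allele_table`, which is how published frequency tables
become first-class inputs for calling and selection without any reads.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .assign_count import AlleleTable, Electropherogram, TopAlleles
from .calling import GenotypeCall, MASDecision, SelectionReport
from .errors import AmpselError

ALLELE_TABLE_COLUMNS = [
    "sample_id",
    "marker",
    "total_reads",
    "marker_reads",
    "allele1",
    "freq1",
    "allele2",
    "freq2",
    "allele3",
    "freq3",
    "allele4",
    "freq4",
]


def _fmt_allele(a) -> str:
    return "NA" if a is None else str(a)


def write_allele_table(tops: list[TopAlleles], path: str | Path) -> None:
    """Write top-allele rows in the report column shape (2-decimal, NA-padded)."""
    rows = []
    for t in tops:
        row = {
            "sample_id": t.sample_id,
            "marker": t.marker,
            "total_reads": t.total_sample_reads,
            "marker_reads": t.total_marker_reads,
        }
        for i in range(4):
            if i < len(t.entries):
                allele, _count, freq = t.entries[i]
                row[f"allele{i + 1}"] = _fmt_allele(allele)
                row[f"freq{i + 1}"] = f"{freq:.2f}"
            else:
                row[f"allele{i + 1}"] = "NA"
                row[f"freq{i + 1}"] = "NA"
        rows.append(row)
    pd.DataFrame(rows, columns=ALLELE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_allele_table(path: str | Path) -> list[TopAlleles]:
    """Read an allele_table.tsv back into TopAlleles records.

    Counts are reconstructed as round(freq * marker_reads); allele keys
    that parse as integers become bp lengths, anything else stays a string
    (haplotype name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ALLELE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AmpselError(f"allele table {path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        marker_reads = int(row["marker_reads"])
        entries = []
        for i in range(4):
            a, f = row[f"allele{i + 1}"], row[f"freq{i + 1}"]
            if pd.isna(a) or a == "NA" or pd.isna(f) or f == "NA":
                continue
            try:
                allele: object = int(a)
            except ValueError:
                allele = a
            freq = float(f)
            entries.append((allele, int(round(freq * marker_reads)), freq))
        out.append(
            TopAlleles(
                sample_id=str(row["sample_id"]),
                marker=str(row["marker"]),
                entries=entries,
                total_marker_reads=marker_reads,
                total_sample_reads=int(row["total_reads"]),
                no_data=marker_reads == 0,
            )
        )
    return out


def top_alleles_to_table(top: TopAlleles) -> AlleleTable:
    """Rebuild a (truncated) AlleleTable from a top-allele record."""
    table = AlleleTable(
        sample_id=top.sample_id,
        marker=top.marker,
        total_sample_reads=top.total_sample_reads,
    )
    for allele, count, _freq in top.entries:
        table.add(allele, count)
    # counts derived from rounded frequencies may not reach the true total;
    # keep the reported marker total as the frequency denominator
    table.total_marker_reads = top.total_marker_reads
    return table


def write_genotypes(calls: list[GenotypeCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "marker": c.marker,
            "ploidy": c.ploidy,
            "genotype": c.rendering,
            "flags": ";".join(sorted(c.flags)) if c.flags else "",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample_id", "marker", "ploidy", "genotype", "flags"]).to_csv(
        path, sep="\t", index=False
    )


def write_mas_decisions(
    decisions: list[MASDecision], tops: dict[tuple[str, str], TopAlleles], path: str | Path
) -> None:
    """MAS report shaped like the allele table plus target frequency/evaluation."""
    rows = []
    for d in decisions:
        t = tops.get((d.sample_id, d.marker))
        row = {
            "sample_id": d.sample_id,
            "marker": d.marker,
            "total_reads": t.total_sample_reads if t else 0,
            "marker_reads": t.total_marker_reads if t else 0,
        }
        for i in range(4):
            if t and i < len(t.entries):
                allele, _c, freq = t.entries[i]
                row[f"allele{i + 1}"] = _fmt_allele(allele)
                row[f"freq{i + 1}"] = f"{freq:.2f}"
            else:
                row[f"allele{i + 1}"] = "NA"
                row[f"freq{i + 1}"] = "NA"
        row["target_allele"] = _fmt_allele(d.target_allele)
        row["target_frequency"] = f"{d.target_frequency:.2f}"
        row["evaluation"] = d.label
        rows.append(row)
    cols = ALLELE_TABLE_COLUMNS + ["target_allele", "target_frequency", "evaluation"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_selection(report: SelectionReport, required_markers: list[str], path: str | Path) -> None:
    rows = []
    for sid in sorted(report.selected):
        failing = [
            m
            for m in required_markers
            for d in report.decisions[sid]
            if d.marker == m and not d.carries
        ]
        rows.append(
            {
                "sample_id": sid,
                "selected": "yes" if report.selected[sid] else "no",
                "failing_markers": ";".join(failing),
            }
        )
    pd.DataFrame(rows, columns=["sample_id", "selected", "failing_markers"]).to_csv(
        path, sep="\t", index=False
    )


def write_electropherogram_tsv(egram: Electropherogram, path: str | Path) -> None:
    pd.DataFrame(egram.trace, columns=["length", "frequency"]).to_csv(path, sep="\t", index=False)


def write_prep_stats(stats, path: str | Path) -> None:
    rows = []
    for sid, entry in sorted(stats.per_sample.items()):
        rows.append({"sample_id": sid, **entry})
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "assigned", "trim_dropped", "merge_failed", "length_filtered", "kept"],
    )
    df.to_csv(path, sep="\t", index=False)
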