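"""End-to-end orchestration: raw reads (or a published frequency table) to
allele tables, genotype calls, selection decisions, and QC reports.

``run_pipeline`` executes readprep → assign/count → calling → qc and
writes every tabular artifact plus a machine-readable manifest (parameter
values, input checksums, and a read-conservation ledger). It is
deterministic: rerunning on identical inputs produces byte-identical
TSVs.

``tables_only_entrypoint`` enters the same calling/selection/qc stages
from an ``allele_table.tsv``, so a frequency table transcribed from a
report is as good an input as a FASTQ library.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assign_count import (
    AlleleTable,
    MarkerAssigner,
    TopAlleles,
    export_electropherogram,
    top_alleles,
)
from .calling import (
    CallingParams,
    GenotypeCall,
    call_diploid,
    call_polyploid,
    evaluate_mas,
    select_individuals,
)
from .errors import AmpselError, StageError
from .panel import MarkerPanel, load_panel
from .qc import marker_read_proportions
from .readprep import prep_reads
from .report_io import (
    read_allele_table,
    top_alleles_to_table,
    write_allele_table,
    write_electropherogram_tsv,
    write_genotypes,
    write_mas_decisions,
    write_prep_stats,
    write_selection,
)

log = logging.getLogger("ampsel")


@dataclass
class RunConfig:
    panel: str
    r1: str | None = None
    r2: str | None = None
    index_r1: str | None = None
    index_r2: str | None = None
    allele_table: str | None = None
    out_dir: str = "ampsel_out"
    max_index_mismatch: int = 0
    max_primer_mismatch: int = 2
    q_threshold: int = 20
    min_overlap: int = 10
    max_mismatch_density: float = 0.05
    min_length: int = 80
    required_markers: list[str] | None = None
    calling: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise StageError("validate", f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not Path(self.panel).exists():
            raise StageError("validate", f"panel config not found: {self.panel}")
        if self.allele_table is None:
            for name in ("r1", "r2"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise StageError("validate", f"FASTQ path missing or absent: {name}={p}")
        elif not Path(self.allele_table).exists():
            raise StageError("validate", f"allele table not found: {self.allele_table}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _call_for_sample(
    top: TopAlleles, ploidy: int, marker, params: CallingParams
) -> GenotypeCall | None:
    if marker.marker_class == "dominant":
        return None  # presence/absence marker: judged by MAS fraction, not genotype
    if ploidy == 2:
        return call_diploid(top, marker, params)
    if ploidy >= 2:
        return call_polyploid(top, ploidy, marker, params)
    # haploid: single best-supported allele
    call = GenotypeCall(sample_id=top.sample_id, marker=top.marker, ploidy=1)
    if top.no_data or not top.entries:
        call.flags.add("no-call")
    else:
        call.alleles_with_dosage = [(top.entries[0][0], 1)]
    return call


def _downstream(
    panel: MarkerPanel,
    tables: dict[tuple[str, str], AlleleTable],
    tops: dict[tuple[str, str], TopAlleles],
    out_dir: Path,
    required_markers: list[str] | None,
    params: CallingParams,
) -> dict:
    """Calling + MAS + QC from allele tables; shared by both entrypoints."""
    ploidy_of = {s.sample_id: s.ploidy for s in panel.samples}
    marker_of = {m.name: m for m in panel.markers}

    calls = []
    for (sid, mname), top in sorted(tops.items()):
        marker = marker_of.get(mname)
        if marker is None:
            continue
        call = _call_for_sample(top, ploidy_of.get(sid, 2), marker, params)
        if call is not None:
            calls.append(call)
    write_genotypes(calls, out_dir / "genotypes.tsv")

    mas_markers = [m for m in panel.markers if m.carrier_threshold is not None and m.target_alleles]
    decisions = []
    sample_ids = sorted({sid for sid, _ in tops})
    for sid in sample_ids:
        for marker in mas_markers:
            table = tables.get((sid, marker.name))
            if table is None:
                table = AlleleTable(sample_id=sid, marker=marker.name)
            decisions.append(evaluate_mas(table, marker))
    write_mas_decisions(decisions, tops, out_dir / "mas_decisions.tsv")

    required = required_markers if required_markers is not None else [m.name for m in mas_markers]
    selection = None
    if decisions and required:
        selection = select_individuals(decisions, required)
        write_selection(selection, required, out_dir / "selection.tsv")

    proportions = marker_read_proportions(list(tables.values()), scope="cohort")
    with open(out_dir / "qc_proportions.tsv", "w") as fh:
        fh.write("scope\tmarker\tproportion\n")
        for m, p in sorted(proportions.proportions.items()):
            fh.write(f"cohort\t{m}\t{p:.4f}\n")
        fh.write(f"cohort\ton_target_sum\t{proportions.on_target_sum:.4f}\n")
        fh.write(f"cohort\tunassigned\t{proportions.unassigned_fraction:.4f}\n")
        fh.write(f"cohort\tbias\t{proportions.bias:.4f}\n")

    return {
        "n_genotype_calls": len(calls),
        "n_mas_decisions": len(decisions),
        "selected_samples": selection.selected_samples() if selection else [],
        "on_target_sum": proportions.on_target_sum,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Full pipeline from paired FASTQ; returns the manifest dict.

    Raises StageError (caught by the CLI as exit status 2/3) on invalid
    configuration or stage failure.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(cfg.panel)
    params = CallingParams(**cfg.calling)

    log.info("readprep: demultiplexing and merging %s / %s", cfg.r1, cfg.r2)
    index_paths = (cfg.index_r1, cfg.index_r2) if cfg.index_r1 and cfg.index_r2 else None
    merged, stats = prep_reads(
        cfg.r1,
        cfg.r2,
        panel,
        max_index_mismatch=cfg.max_index_mismatch,
        q_threshold=cfg.q_threshold,
        min_overlap=cfg.min_overlap,
        max_mismatch_density=cfg.max_mismatch_density,
        min_length=cfg.min_length,
        index_paths=index_paths,
    )
    write_prep_stats(stats, out_dir / "readprep_stats.tsv")

    log.info("assign_count: primer assignment over %d samples", len(merged))
    assigner = MarkerAssigner(panel, cfg.max_primer_mismatch)
    marker_of = {m.name: m for m in panel.markers}
    tables: dict[tuple[str, str], AlleleTable] = {}
    primer_unassigned: dict[str, int] = {}
    for sid, reads in merged.items():
        n_enter = len(reads)
        primer_unassigned[sid] = 0
        for read in reads:
            mname = assigner.assign(read.sequence)
            if mname is None:
                primer_unassigned[sid] += 1
                continue
            key = (sid, mname)
            if key not in tables:
                tables[key] = AlleleTable(sample_id=sid, marker=mname)
            marker = marker_of[mname]
            tables[key].add(read.sequence if marker.marker_class == "SNP" else read.length)
        for key in tables:
            if key[0] == sid:
                tables[key].total_sample_reads = n_enter

    tops = {key: top_alleles(table) for key, table in tables.items()}
    write_allele_table([tops[k] for k in sorted(tops)], out_dir / "allele_table.tsv")

    egram_dir = out_dir / "electropherograms"
    egram_dir.mkdir(exist_ok=True)
    for (sid, mname), table in sorted(tables.items()):
        if marker_of[mname].marker_class in ("SSR", "indel"):
            write_electropherogram_tsv(
                export_electropherogram(table), egram_dir / f"{sid}_{mname}.tsv"
            )

    summary = _downstream(panel, tables, tops, out_dir, cfg.required_markers, params)

    conservation = {
        "input_pairs": stats.n_input,
        "unassigned_index": stats.n_unassigned,
        "assigned": sum(e["assigned"] for e in stats.per_sample.values()),
        "primer_unassigned": sum(primer_unassigned.values()),
        "counted": sum(t.total_marker_reads for t in tables.values()),
    }
    manifest = {
        "ampsel_version": __version__,
        "parameters": {
            "max_index_mismatch": cfg.max_index_mismatch,
            "max_primer_mismatch": cfg.max_primer_mismatch,
            "q_threshold": cfg.q_threshold,
            "min_overlap": cfg.min_overlap,
            "max_mismatch_density": cfg.max_mismatch_density,
            "min_length": cfg.min_length,
            "calling": cfg.calling,
            "seed": cfg.seed,
        },
        "inputs": {
            "panel": _sha256(cfg.panel),
            "r1": _sha256(cfg.r1),
            "r2": _sha256(cfg.r2),
        },
        "conservation": conservation,
        "summary": summary,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def tables_only_entrypoint(
    allele_table_path: str | Path,
    panel: MarkerPanel,
    out_dir: str | Path,
    required_markers: list[str] | None = None,
    calling_params: CallingParams | None = None,
) -> dict:
    """Calling + MAS + QC directly from an allele_table.tsv.

    Produces the same genotype and selection outputs the full pipeline
    would emit from equivalent counts. An empty table yields empty outputs
    and succeeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tops_list = read_allele_table(allele_table_path)
    tops = {(t.sample_id, t.marker): t for t in tops_list}
    tables = {key: top_alleles_to_table(t) for key, t in tops.items()}
    params = calling_params or CallingParams()
    try:
        return _downstream(panel, tables, tops, out_dir, required_markers, params)
    except AmpselError as exc:
        raise StageError("calling", str(exc)) from exc
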