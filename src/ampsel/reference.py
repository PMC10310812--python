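"""Packaged reference tables and demo marker definitions.

Two published-style frequency tables ship with the package as TSVs:

* ``apple_cultivar_allele_frequencies.tsv`` — four diploid and four
  triploid apple cultivars at a flesh-mealiness SSR (MdPG1.mod, repeat
  unit 3) and a disease-resistance indel (Alt_indel), with the expected
  genotype for each row.
* ``pear_seedling_mas_frequencies.tsv`` — a cross-parent pair plus ten
  pear seedlings at three selection markers (scab resistance, ripening
  day, skin color) with per-marker target alleles and thresholds.

The primer sequences attached to the demo marker definitions are
synthetic placeholders (the tables carry frequencies, not primers);
frequency-table workflows never touch them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assign_count import TopAlleles
from .panel import MarkerDef

# Synthetic placeholder primers: valid, mutually distinct 20-mers.
_P = {
    "MdPG1.mod": ("ATCGGATTACCAGGTTCACA", "TGGTCAACCTTGATCGTACC"),
    "Alt_indel": ("CAGGTTCGATAACGGATTCC", "AGGATCCGTTAACTGGTCAA"),
    "TsuENH157.mod": ("GATTCCAGGATTCAGCTACA", "CCATTGACGTTAGGATCAGT"),
    "PPACS2": ("TTACGGACCATTCAGATGCA", "GACCTTAGCATTCGGTACCA"),
    "Psc07": ("ACGATTAGGCCATTCAGTCA", "TTCAGGACCGTTAGCATACC"),
}


def apple_demo_markers() -> list[MarkerDef]:
    """Markers matching the apple genotyping table (synthetic primers)."""
    return [
        MarkerDef(
            name="MdPG1.mod",
            trait="Flesh mealiness",
            marker_class="SSR",
            fwd_primer=_P["MdPG1.mod"][0],
            rev_primer=_P["MdPG1.mod"][1],
            ref_amplicon_length=108,
            repeat_unit=3,
        ),
        MarkerDef(
            name="Alt_indel",
            trait="Alternaria blotch susceptibility",
            marker_class="indel",
            fwd_primer=_P["Alt_indel"][0],
            rev_primer=_P["Alt_indel"][1],
            ref_amplicon_length=162,
        ),
    ]


def pear_mas_markers() -> list[MarkerDef]:
    """The three pear selection markers with their target alleles/thresholds."""
    return [
        MarkerDef(
            name="TsuENH157.mod",
            trait="Pear scab resistance",
            marker_class="SSR",
            fwd_primer=_P["TsuENH157.mod"][0],
            rev_primer=_P["TsuENH157.mod"][1],
            ref_amplicon_length=129,
            repeat_unit=2,
            target_alleles=[127],
            carrier_threshold=0.30,
            carrier_label="Resistant",
            noncarrier_label="Susceptible",
        ),
        MarkerDef(
            name="PPACS2",
            trait="Fruit-ripening day",
            marker_class="SSR",
            fwd_primer=_P["PPACS2"][0],
            rev_primer=_P["PPACS2"][1],
            ref_amplicon_length=114,
            repeat_unit=2,
            target_alleles=[132],
            carrier_threshold=0.20,
            carrier_label="Early harvesting",
            noncarrier_label="Late harvesting",
        ),
        MarkerDef(
            name="Psc07",
            trait="Fruit skin color",
            marker_class="SSR",
            fwd_primer=_P["Psc07"][0],
            rev_primer=_P["Psc07"][1],
            ref_amplicon_length=119,
            repeat_unit=2,
            target_alleles=[151],
            carrier_threshold=0.10,
            carrier_label="Red",
            noncarrier_label="Green",
        ),
    ]


def _load_tsv(name: str) -> pd.DataFrame:
    with resources.files("ampsel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _row_to_top(row: pd.Series) -> TopAlleles:
    entries = []
    marker_reads = int(row["marker_reads"])
    for i in range(1, 5):
        a, f = row[f"allele{i}"], row[f"freq{i}"]
        if pd.isna(a) or a == "NA":
            continue
        freq = float(f)
        entries.append((int(a), int(round(freq * marker_reads)), freq))
    return TopAlleles(
        sample_id=row["sample_id"],
        marker=row["marker"],
        entries=entries,
        total_marker_reads=marker_reads,
        total_sample_reads=int(row["total_reads"]),
    )


def load_apple_genotyping_table() -> tuple[list[TopAlleles], dict]:
    """Apple cultivar frequencies plus {(sample, marker): (ploidy, genotype)}."""
    df = _load_tsv("apple_cultivar_allele_frequencies.tsv")
    tops = [_row_to_top(r) for _, r in df.iterrows()]
    expected = {
        (r["sample_id"], r["marker"]): (int(r["ploidy"]), r["predicted_genotype"])
        for _, r in df.iterrows()
    }
    return tops, expected


def load_pear_mas_table() -> tuple[list[TopAlleles], dict]:
    """Pear seedling frequencies plus {(sample, marker): (target_freq, evaluation)}."""
    df = _load_tsv("pear_seedling_mas_frequencies.tsv")
    tops = [_row_to_top(r) for _, r in df.iterrows()]
    expected = {
        (r["sample_id"], r["marker"]): (float(r["target_frequency"]), r["evaluation"])
        for _, r in df.iterrows()
    }
    return tops, expected
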