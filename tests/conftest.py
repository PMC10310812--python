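import numpy as np
import pytest

from ampsel.panel import MarkerDef, MarkerPanel, PrimerScheme, SampleRecord

FWD_A = "ATCGGATTACCAGGTTCACA"
REV_A = "TGGTCAACCTTGATCGTACC"
FWD_B = "CAGGTTCGATAACGGATTCC"
REV_B = "AGGATCCGTTAACTGGTCAA"
FWD_SNP = "GATTCCAGGATTCAGCTACA"
REV_SNP = "CCATTGACGTTAGGATCAGT"

INDEX_PAIRS = [
    ("AACCGGTT", "TTGGCCAA"),
    ("ACACGTGT", "TGTGCACA"),
    ("AAGGCCTT", "TTCCGGAA"),
    ("AGAGCTCT", "TCTCGAGA"),
    ("ATATCGCG", "TATAGCGC"),
    ("AATTCCGG", "TTAAGGCC"),
]


def make_marker_ssr(name="SSR_A", unit=2, ref_len=127, **kw):
    return MarkerDef(
        name=name,
        marker_class="SSR",
        fwd_primer=FWD_A,
        rev_primer=REV_A,
        ref_amplicon_length=ref_len,
        repeat_unit=unit,
        **kw,
    )


def make_panel(n_samples=3, ploidies=None, markers=None):
    if markers is None:
        markers = [
            make_marker_ssr("SSR_A", unit=2, ref_len=127, target_alleles=[127],
                            carrier_threshold=0.30, carrier_label="Resistant",
                            noncarrier_label="Susceptible"),
            MarkerDef(
                name="SSR_B",
                marker_class="SSR",
                fwd_primer=FWD_B,
                rev_primer=REV_B,
                ref_amplicon_length=108,
                repeat_unit=3,
            ),
        ]
    ploidies = ploidies or [2] * n_samples
    samples = [
        SampleRecord(f"s{i:02d}", i5, i7, ploidy=p)
        for i, ((i5, i7), p) in enumerate(zip(INDEX_PAIRS[:n_samples], ploidies))
    ]
    return MarkerPanel(scheme=PrimerScheme(), markers=markers, samples=samples)


@pytest.fixture
def toy_panel():
    return make_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
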