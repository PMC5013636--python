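import numpy as np
import pytest

from sccprog.spectrum import VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_variant(
    sample="P1_NS",
    pos=10,
    ref="C",
    alt="T",
    chrom="chr1",
    patient=None,
    lesion_class=None,
    vaf=0.2,
    gene=None,
    cosmic_count=None,
):
    """Variant factory with sensible defaults for toy constructions."""
    if patient is None:
        patient = sample.split("_")[0]
    if lesion_class is None:
        lesion_class = sample.split("_")[1] if "_" in sample else "NS"
    return VariantRecord(
        patient=patient,
        sample=sample,
        lesion_class=lesion_class,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        gene=gene,
        cosmic_count=cosmic_count,
    )


@pytest.fixture
def toy_reference():
    # 60 bp of mixed composition, 1-based coordinates
    seq = "ACATGCGTACCTTAGCAGCTACGTTCAGGATCCGATCGATTGCACGTGCAATGCCGGTAA"
    return {"chr1": seq}
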