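import textwrap

import pyfaidx
import pytest

from pansubtypes.io_profiles import GeneCatalog, MutationRecord


@pytest.fixture()
def toy_fasta(tmp_path):
    """Two small contigs with known trinucleotide contexts, plus an MT decoy."""
    seq1 = "TACGATGCATTNACGT"  # 1-based: pos3=C in ACG; pos7=G in TGC; pos12=N
    path = tmp_path / "toy.fa"
    path.write_text(textwrap.dedent(f"""\
        >1
        {seq1}
        >MT
        AACGTT
        """))
    return pyfaidx.Fasta(str(path), as_raw=True)


def make_record(sample="S1", donor="D1", chrom="1", pos=3, ref="C", alt="T",
                gene="G1", cons="missense_variant", ctype="CT1"):
    return MutationRecord(
        sample_id=sample, donor_id=donor, chromosome=chrom, position=pos,
        ref_allele=ref, alt_allele=alt, gene_id=gene, consequence=cons,
        cancer_type=ctype)


@pytest.fixture()
def record_factory():
    return make_record


@pytest.fixture()
def small_catalog():
    return GeneCatalog({
        "G1": ("G1", True),
        "G2": ("G2", True),
        "G3": ("G3", True),
        "NC1": ("NC1", False),
    })
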