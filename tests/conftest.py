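"""Shared fixtures: tiny hand-checkable pedigrees, variants, and VCF writers."""

import textwrap

import pytest
from hypothesis import HealthCheck, settings

from famscreen import (
    Affection,
    Consequence,
    Individual,
    Pedigree,
    VariantRecord,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_variant(
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    panel_af=None,
    **kwargs,
):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        panel_af=panel_af,
        **kwargs,
    )


@pytest.fixture
def make_trio():
    """Father + mother + one child pedigree with configurable affection."""

    def build(father_aff=Affection.AFFECTED, mother_aff=Affection.UNAFFECTED,
              child_aff=Affection.AFFECTED, family_id="FAM_T"):
        return Pedigree(
            family_id=family_id,
            members=[
                Individual("dad", family_id, affection=father_aff),
                Individual("mum", family_id, affection=mother_aff),
                Individual("kid", family_id, father_id="dad", mother_id="mum",
                           affection=child_aff),
            ],
        )

    return build


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write raw VCF text (dedented) to a temp file and return the path."""

    def write(body, name="test.vcf"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(body).lstrip())
        return path

    return write
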