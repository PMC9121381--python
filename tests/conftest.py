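import numpy as np
import pytest

import fmk


@pytest.fixture
def genotype_tsv(tmp_path):
    """Small mixed-class genotype table exercising every cell syntax."""
    path = tmp_path / "genotypes.tsv"
    path.write_text(
        "Sample\tPopulation\tSex\tD1S1\tDXS1\tDYS1\n"
        "s1\tPopA\tmale\t12/13\t21\t13-14\n"
        "s2\tPopA\tfemale\t12/12\t21/22\t.\n"
        "s3\tPopB\tmale\t14.2/12\t22\t15-16\n"
        "s4\tPopA\tmale\t13/13\t21\t13-14\n"
    )
    return path


@pytest.fixture
def marker_classes():
    return {"D1S1": "autosomal_str", "DXS1": "x_str", "DYS1": "y_str"}


@pytest.fixture
def toy_alignment():
    """The three-sequence worked example: S=2, k=4/3, Hd=1."""
    return fmk.SequenceAlignment(records=[
        ("a", "P", "AAA"), ("b", "P", "AAT"), ("c", "P", "ATT")])


@pytest.fixture
def str_panel():
    """54 STR-like loci with Dirichlet(1) frequencies over 10 alleles."""
    return fmk.sample_allele_freqs(10, 1.0, seed=7, n_loci=54, prefix="STR")


@pytest.fixture
def snp_panel():
    """133 biallelic SNP-like loci."""
    return fmk.sample_allele_freqs(2, 1.0, seed=8, n_loci=133, prefix="SNP",
                                   marker_class="autosomal_snp")


def merge_tables(a: fmk.FrequencyTable, b: fmk.FrequencyTable
                 ) -> fmk.FrequencyTable:
    return fmk.FrequencyTable(
        freqs={**a.freqs, **b.freqs},
        gene_counts={**a.gene_counts, **b.gene_counts},
        marker_class={**a.marker_class, **b.marker_class})
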