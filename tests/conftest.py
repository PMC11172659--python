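import numpy as np
import pandas as pd
import pytest

from holowas.io import GenotypeMatrix, OTUTable, PhenotypeTable
from holowas.simulate import SimConfig, sim_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but fully structured synthetic dataset shared across tests."""
    cfg = SimConfig(n=60, q=80, p=30, h2_g=0.3, h2_m=0.2, residual=0.5, seed=42)
    genotypes, otus, kernels, phenos, causal = sim_dataset(cfg)
    return {
        "cfg": cfg,
        "genotypes": genotypes,
        "otus": otus,
        "kernels": kernels,
        "phenos": phenos,
        "causal": causal,
    }


@pytest.fixture()
def plink_fixture(tmp_path):
    """Hand-written 3-sample, 2-SNP PLINK1 fileset with known genotypes.

    Alt-allele dosages (A1 counted): SNP1 = (2, 1, 0); SNP2 = (0, NA, 1).
    """
    prefix = tmp_path / "toy"
    (tmp_path / "toy.fam").write_text(
        "f1 ind1 0 0 1 -9\nf2 ind2 0 0 2 -9\nf3 ind3 0 0 1 -9\n"
    )
    (tmp_path / "toy.bim").write_text(
        "1\tsnpA\t0\t1000\tA\tG\n2\tsnpB\t0\t2000\tC\tT\n"
    )
    # 2-bit codes little-endian: 00=hom A1 (2), 10=het (1), 11=hom A2 (0), 01=missing
    (tmp_path / "toy.bed").write_bytes(b"\x6c\x1b\x01\x38\x27")
    expected = np.array([[2.0, 0.0], [1.0, np.nan], [0.0, 1.0]])
    return str(prefix), expected


@pytest.fixture()
def vcf_fixture(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1\n"
    )
    expected = np.array([[0.0, np.nan], [1.0, 0.0], [2.0, 1.0]])
    return str(path), expected


@pytest.fixture()
def gff_fixture(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(
        "##gff-version 3\n"
        "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=geneA;Name=GENE_A;biotype=protein_coding\n"
        "1\tsrc\tgene\t101000\t102000\t.\t-\t.\tID=geneB;Name=GENE_B\n"
        "2\tsrc\tgene\t500\t900\t.\t+\t.\tID=geneC;Name=GENE_C\n"
    )
    return str(path)


@pytest.fixture()
def simple_otu_table():
    return OTUTable(
        ["a", "b"], ["o1", "o2"], np.array([[0.6, 0.4], [0.2, 0.8]])
    )


@pytest.fixture()
def simple_phenotypes():
    df = pd.DataFrame(
        {"y": [1.0, 2.0, 3.0], "age": [4.0, 5.0, 6.0]},
        index=["a", "b", "c"],
    )
    return PhenotypeTable(df, traits=["y"], covariates=["age"])
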