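"""Panel I/O: dialect round trips, ancestral recoding, and validation errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapclock import hapio
from hapclock.types import MISSING, HapclockError, PhasedPanel, SiteAnnotation

from conftest import make_panel


def write_read(panel, tmp_path, dialect):
    target = tmp_path / ("panel" if dialect == "impute" else f"panel.{dialect}")
    hapio.write_phased_panel(panel, target, dialect)
    # VCF carries no population labels, so supply the sample -> population map
    pops = (
        dict(zip((s for s, _ in panel.chrom_ids), panel.populations))
        if dialect == "vcf"
        else None
    )
    return hapio.read_phased_panel(
        target, dialect, annotation=panel.sites, populations=pops
    )


@st.composite
def panels(draw):
    n_samples = draw(st.integers(1, 4))
    n_sites = draw(st.integers(1, 6))
    alleles = draw(
        st.lists(
            st.lists(st.sampled_from([0, 1, MISSING]), min_size=n_sites, max_size=n_sites),
            min_size=2 * n_samples,
            max_size=2 * n_samples,
        )
    )
    positions = sorted(
        draw(
            st.lists(
                st.integers(1, 10_000), min_size=n_sites, max_size=n_sites, unique=True
            )
        )
    )
    pops = draw(
        st.lists(st.sampled_from(["CEU", "YRI", "CHB"]), min_size=n_samples, max_size=n_samples)
    )
    sites = [
        SiteAnnotation(f"rs{k}", p, "C", "T") for k, p in enumerate(positions)
    ]
    return PhasedPanel(
        sites=sites,
        chrom_ids=[(f"ind{i}", h) for i in range(n_samples) for h in (0, 1)],
        populations=[pops[i] for i in range(n_samples) for _ in (0, 1)],
        alleles=np.array(alleles, dtype=np.int8),
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(panel=panels(), dialect=st.sampled_from(hapio.DIALECTS))
def test_round_trip_preserves_panel(panel, dialect, tmp_path_factory):
    """Writing then reading any dialect reproduces the allele matrix bit-exactly."""
    tmp = tmp_path_factory.mktemp("rt")
    back = write_read(panel, tmp, dialect)
    np.testing.assert_array_equal(back.alleles, panel.alleles)
    assert back.chrom_ids == panel.chrom_ids
    assert back.populations == panel.populations
    assert [s.position for s in back.sites] == [s.position for s in panel.sites]


def test_tsv_all_ancestral_reads_as_zeros(tmp_path):
    panel = make_panel([[0, 0, 0], [0, 0, 0]])
    back = write_read(panel, tmp_path, "tsv")
    assert not back.alleles.any()


def test_vcf_phased_het_splits_into_haplotypes(tmp_path):
    """A 0|1 record maps chromosome A to code 0 and chromosome B to code 1."""
    vcf = tmp_path / "one.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=15,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "15\t10\trs1\tA\tG\t.\t.\t.\tGT\t0|1\n"
    )
    panel = hapio.read_phased_panel(vcf, "vcf")
    assert panel.alleles.tolist() == [[0], [1]]
    assert panel.chrom_ids == [("S1", 0), ("S1", 1)]


def test_vcf_recoding_against_annotation_flips_when_alt_is_ancestral(tmp_path):
    """Recoding involution: swapping ancestral/derived flips every non-missing code."""
    vcf = tmp_path / "one.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=15,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "15\t10\trs1\tA\tG\t.\t.\t.\tGT\t0|1\n"
        "15\t20\trs2\tC\tT\t.\t.\t.\tGT\t.|1\n"
    )
    forward = [
        SiteAnnotation("rs1", 10, "A", "G"),
        SiteAnnotation("rs2", 20, "C", "T"),
    ]
    flipped = [
        SiteAnnotation("rs1", 10, "G", "A"),
        SiteAnnotation("rs2", 20, "T", "C"),
    ]
    a = hapio.read_phased_panel(vcf, "vcf", annotation=forward).alleles
    b = hapio.read_phased_panel(vcf, "vcf", annotation=flipped).alleles
    observed = a != MISSING
    assert (a[observed] + b[observed] == 1).all()
    assert (b[~observed] == MISSING).all()


def test_vcf_unphased_heterozygote_is_an_error(tmp_path):
    vcf = tmp_path / "bad.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=15,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "15\t10\trs1\tA\tG\t.\t.\t.\tGT\t0/1\n"
    )
    with pytest.raises(HapclockError, match="S1.*rs1|rs1.*S1"):
        hapio.read_phased_panel(vcf, "vcf")


def test_vcf_allele_mismatch_against_annotation_is_an_error(tmp_path):
    vcf = tmp_path / "bad.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=15,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "15\t10\trs1\tA\tG\t.\t.\t.\tGT\t0|1\n"
    )
    wrong = [SiteAnnotation("rs1", 10, "C", "T")]
    with pytest.raises(HapclockError, match="do not match"):
        hapio.read_phased_panel(vcf, "vcf", annotation=wrong)


def test_impute_duplicate_site_id_is_an_error(tmp_path):
    (tmp_path / "p.legend").write_text("id position a0 a1\nrs1 5 A G\nrs1 9 C T\n")
    (tmp_path / "p.haps").write_text("0 0\n1 1\n")
    (tmp_path / "p.sample").write_text("ID_1 ID_2 missing\n0 0 0\n1 ind0 0\n")
    with pytest.raises(HapclockError, match="duplicate site_id"):
        hapio.read_phased_panel(tmp_path / "p", "impute")


def test_haplotype_definition_reader_rejects_unknown_nickname(tmp_path):
    path = tmp_path / "defs.tsv"
    path.write_text("name\tderived_sites\nC1\t\nC2\tc9\n")
    with pytest.raises(HapclockError, match="unknown site nicknames"):
        hapio.read_haplotype_definitions(path, site_universe=["c1", "c11"])


def test_write_tables_empty_assignment_gives_header_only(tmp_path):
    empty = pd.DataFrame(columns=["sample", "hap_index", "population", "label"])
    out = tmp_path / "empty.tsv"
    hapio.write_tables(empty, out)
    assert out.read_text() == "sample\thap_index\tpopulation\tlabel\n"


def test_write_tables_single_node_network_dot(tmp_path):
    from hapclock.hapnetwork import build_network

    panel = make_panel([[0, 1], [0, 1]])
    net = build_network(panel, min_variant_freq=0.0)
    out = tmp_path / "net.dot"
    hapio.write_tables(net, out, format="dot")
    text = out.read_text()
    assert text.count("--") == 0
    assert text.count('shape=') == 1


def test_write_tables_counts_conserve_totals(tmp_path):
    counts = pd.DataFrame(
        {"CEU": [3, 1], "YRI": [0, 5]}, index=pd.Index(["C1", "C2"], name="haplotype")
    )
    out = tmp_path / "counts.tsv"
    hapio.write_tables(counts, out)
    back = pd.read_csv(out, sep="\t", index_col=0)
    assert back.to_numpy().sum() == counts.to_numpy().sum()
    assert list(back.sum(axis=0)) == list(counts.sum(axis=0))


def test_pairwise_alignment_reader_requires_two_sequences(tmp_path):
    fasta = tmp_path / "aln.fa"
    fasta.write_text(">a\nACGT\n")
    with pytest.raises(HapclockError, match="exactly 2"):
        hapio.read_pairwise_alignment(fasta)
    fasta.write_text(">a\nAC-GT\n>b\nACCGT\n")
    aln = hapio.read_pairwise_alignment(fasta)
    assert len(aln) == 5
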