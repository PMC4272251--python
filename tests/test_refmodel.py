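import io

import numpy as np
import pytest

from mthet.errors import ConfigError, DataError
from mthet.refmodel import (
    GenomeRegion,
    annotate_variant,
    load_reference,
    read_bed_regions,
    reverse_complement,
    translate_codon,
)
from mthet.synthetic_reference import build_synthetic_rcrs, fasta_text, gene_table_text


def test_packaged_reference_has_rcrs_structure(rcrs):
    assert rcrs.length == 16569
    assert rcrs.base(3107) == "N"
    polyc = rcrs.polyc_region
    assert (polyc.start, polyc.end) == (16184, 16193)
    assert polyc.width(rcrs.length) == 10


def test_packaged_files_match_generator(rcrs):
    model = build_synthetic_rcrs()
    assert model.sequence == rcrs.sequence
    # regenerating the packaged text reproduces it bit for bit
    regenerated = load_reference(io.StringIO(fasta_text(model)), io.StringIO(gene_table_text()))
    assert regenerated.sequence == rcrs.sequence
    assert len(regenerated.genes) == len(rcrs.genes)


def test_wrapping_region_width_and_membership():
    region = GenomeRegion(16024, 576, "CR")
    assert region.width(16569) == (16569 - 16024 + 1) + 576
    assert region.contains(16500, 16569)
    assert region.contains(250, 16569)
    assert not region.contains(10000, 16569)


def test_toy_reference_gene_width(toy_reference):
    gene = toy_reference.genes[0]
    assert gene.width(toy_reference.length) == 21
    assert toy_reference.length == 100


def test_load_reference_rejects_missing_polyc(toy_reference):
    fasta = io.StringIO(">toy\n" + toy_reference.sequence + "\n")
    with pytest.raises(ConfigError, match="polyC"):
        load_reference(fasta, io.StringIO("# empty annotation\n"))


def test_load_reference_rejects_multi_record_fasta():
    fasta = io.StringIO(">a\nACGT\n>b\nACGT\n")
    ann = io.StringIO("1\t2\tpolyC\tspecial\t+\n")
    with pytest.raises(ConfigError, match="exactly one"):
        load_reference(fasta, ann)


def test_load_reference_rejects_declared_length_mismatch():
    fasta = io.StringIO(">a\nACGTACGT\n")
    ann = io.StringIO("#length=9\n1\t2\tpolyC\tspecial\t+\n")
    with pytest.raises(ConfigError, match="length"):
        load_reference(fasta, ann)


def test_region_out_of_bounds_rejected():
    fasta = io.StringIO(">a\nACGTACGT\n")
    ann = io.StringIO("1\t2\tpolyC\tspecial\t+\n1\t20\tG1\trRNA\t+\n")
    with pytest.raises(ConfigError, match="out of bounds"):
        load_reference(fasta, ann)


@pytest.mark.parametrize(
    "position, ref, alt, gene, feature_class, consequence, in_polyc",
    [
        (5009, "A", "G", "MTND2", "protein-coding", "synonymous", False),
        (2905, "A", "G", "MTRNR2", "rRNA", "noncoding", False),
        (250, "T", "C", "CR", "control", "noncoding", False),
        (16186, "C", "T", "CR", "control", "noncoding", True),
    ],
)
def test_annotation_spot_checks(rcrs, position, ref, alt, gene, feature_class, consequence, in_polyc):
    ann = annotate_variant(rcrs, position, ref, alt)
    assert ann.gene == gene
    assert ann.feature_class == feature_class
    assert ann.consequence == consequence
    assert ann.in_polyC is in_polyc


def test_annotate_ref_mismatch_names_position_and_bases(rcrs):
    actual = rcrs.base(100)
    wrong = "A" if actual != "A" else "C"
    with pytest.raises(DataError) as err:
        annotate_variant(rcrs, 100, wrong, "G" if wrong != "G" else "T")
    msg = str(err.value)
    assert "100" in msg and actual in msg and wrong in msg


def test_annotate_rejects_placeholder_position(rcrs):
    with pytest.raises(DataError, match="3107"):
        annotate_variant(rcrs, 3107, "A", "G")


def test_identity_substitution_never_errors(rcrs):
    rng = np.random.default_rng(11)
    for pos in rng.integers(1, rcrs.length + 1, size=300):
        pos = int(pos)
        base = rcrs.base(pos)
        if base == "N":
            continue
        ann = annotate_variant(rcrs, pos, base, base)
        assert ann.consequence in ("synonymous", "noncoding")


def test_every_position_has_one_primary_feature_class(rcrs):
    rng = np.random.default_rng(5)
    for pos in rng.integers(1, rcrs.length + 1, size=500):
        feature = rcrs.feature_at(int(pos))
        if feature is not None:
            assert feature.feature_class in ("tRNA", "rRNA", "protein-coding", "control")


def test_packaged_coding_genes_have_no_internal_stops(rcrs):
    for gene in rcrs.genes:
        if gene.feature_class != "protein-coding":
            continue
        block = rcrs.sequence[gene.start - 1 : gene.end]
        cds = block if gene.strand == "+" else reverse_complement(block)
        for i in range(0, len(cds) // 3 * 3, 3):
            assert translate_codon(cds[i : i + 3]) != "*", f"stop inside {gene.label} at codon {i // 3}"


def test_reverse_strand_consequence_uses_coding_strand(rcrs):
    nd6 = next(g for g in rcrs.genes if g.label == "MTND6")
    # first coding codon of a reverse-strand gene sits at the gene's END
    ann = annotate_variant(rcrs, nd6.end, rcrs.base(nd6.end), rcrs.base(nd6.end))
    assert ann.gene == "MTND6"
    assert ann.consequence in ("synonymous", "noncoding")


def test_bed_regions_convert_to_one_based_inclusive():
    regions = read_bed_regions(io.StringIO("MT\t9\t30\tmask1\n"), 100)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (10, 30)
    with pytest.raises(DataError):
        read_bed_regions(io.StringIO("MT\t90\t120\n"), 100)
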