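import pytest

from levikit.annotate import (
    GenomeRecord,
    assign_layout,
    extract_replicase_window,
    find_orfs,
    orf_table,
)
from levikit.io import NucleotideSequence, translate


def test_find_orfs_simple_planted_orf():
    genome = NucleotideSequence("g", "AAATGAAAGCTTAAAA")
    orfs = find_orfs(genome, min_protein_length=2)
    assert len(orfs) == 1
    (orf,) = orfs
    assert (orf.start, orf.end) == (2, 14)
    assert orf.protein.seq == "MKA"
    assert not orf.partial


def test_find_orfs_no_start_codon():
    genome = NucleotideSequence("g", "AAACCCTTTCCCAAA")
    assert find_orfs(genome, min_protein_length=1) == []


def test_find_orfs_partial_orf_flagged():
    # ATG then no stop before the contig end
    genome = NucleotideSequence("g", "ATGAAAGCTGCA")
    (orf,) = find_orfs(genome, min_protein_length=2)
    assert orf.partial and orf.end == 12 and orf.protein.seq == "MKAA"


def test_found_orfs_retranslate_consistently(genome_data):
    genomes, _ = genome_data
    for genome in genomes:
        for orf in find_orfs(genome, min_protein_length=30):
            coding = orf.end - 3 if not orf.partial else orf.end
            body = translate(
                NucleotideSequence("t", genome.seq[orf.start : coding] + "TAA")
            )
            assert orf.protein.seq == "M" + body.seq[1:]


def _three_orf_genome():
    """ORFs at M@[0,600), X@[620,1040), Y@[1060,1480), R@[1500,3000)."""

    def orf(n_codons):
        return "ATG" + "GCT" * (n_codons - 1) + "TAA"

    seq = (
        orf(199)  # [0, 600)
        + "A" * 20
        + orf(139)  # [620, 1040)
        + "A" * 20
        + orf(139)  # [1060, 1480)
        + "A" * 20
        + orf(499)  # [1500, 3000)
    )
    return NucleotideSequence("layout", seq)


def test_assign_layout_two_candidates_first_is_primary():
    genome = _three_orf_genome()
    record = GenomeRecord(genome, find_orfs(genome, min_protein_length=100))
    assert [(o.start, o.end) for o in record.orfs] == [
        (0, 600), (620, 1040), (1060, 1480), (1500, 3000)
    ]
    record = assign_layout(record, 0, 1500)
    assert record.layout_complete
    assert [o.start for o in record.cp_candidates] == [620, 1060]
    assert record.primary_cp.start == 620
    assert record.replicase.start == 1500


def test_assign_layout_single_candidate():
    genome = _three_orf_genome()
    record = GenomeRecord(genome, find_orfs(genome, min_protein_length=100))
    # treat the second ORF as maturation: only Y remains between it and R
    record = assign_layout(record, 620, 1500)
    assert [o.start for o in record.cp_candidates] == [1060]
    assert record.primary_cp.start == 1060


def test_assign_layout_missing_hint_incomplete():
    genome = _three_orf_genome()
    record = GenomeRecord(genome, find_orfs(genome, min_protein_length=100))
    record = assign_layout(record, 0, None)
    assert not record.layout_complete
    assert record.cp_candidates == [] and record.primary_cp is None


def test_planted_layout_recovered(genome_data):
    genomes, truths = genome_data
    for genome, truth in zip(genomes, truths):
        record = GenomeRecord(genome, find_orfs(genome, min_protein_length=30))
        found = {(o.start, o.end) for o in record.orfs}
        assert truth.maturation in found
        assert truth.cp in found
        assert truth.replicase in found
        record = assign_layout(record, truth.maturation[0], truth.replicase[0])
        assert record.layout_complete
        assert (record.primary_cp.start, record.primary_cp.end) == truth.cp


def test_extract_window_arithmetic_and_truncation():
    # two-ORF genome: maturation at 0, replicase at 100
    g2 = NucleotideSequence(
        "g2", "ATG" + "GCT" * 20 + "TAA" + "A" * 34 + "ATG" + "GCT" * 30 + "TAA"
    )
    rec = GenomeRecord(g2, find_orfs(g2, min_protein_length=10))
    rec = assign_layout(rec, 0, 100)
    window = extract_replicase_window(rec, flank=20)
    assert window.length == 41 and not window.truncated
    assert window.start_offset == 20
    assert window.rna[20:23] == "AUG"
    assert "T" not in window.rna and "U" in window.rna

    tiny = extract_replicase_window(rec, flank=0)
    assert tiny.length == 1 and not tiny.truncated

    # truncation at the left contig boundary
    g3 = NucleotideSequence("g3", "ATGAA" + "ATG" + "GCT" * 30 + "TAA" + "A" * 40)
    rec3 = GenomeRecord(g3, find_orfs(g3, min_protein_length=10))
    rec3 = assign_layout(rec3, 0, 5)
    win3 = extract_replicase_window(rec3, flank=20)
    assert win3.truncated and win3.length == 26 and win3.start_offset == 5


def test_extract_window_requires_replicase(genome_data):
    genomes, _ = genome_data
    record = GenomeRecord(genomes[0], find_orfs(genomes[0], 30))
    with pytest.raises(ValueError, match="replicase"):
        extract_replicase_window(record, 20)


def test_window_length_bound(genome_data):
    genomes, truths = genome_data
    for genome, truth in zip(genomes, truths):
        record = GenomeRecord(genome, find_orfs(genome, 30))
        record = assign_layout(record, truth.maturation[0], truth.replicase[0])
        for flank in (0, 5, 20, 5000):
            window = extract_replicase_window(record, flank)
            assert window.length <= 2 * flank + 1
            assert window.truncated == (window.length < 2 * flank + 1)


def test_orf_table_renders(genome_data):
    genomes, truths = genome_data
    record = GenomeRecord(genomes[0], find_orfs(genomes[0], 30))
    record = assign_layout(record, truths[0].maturation[0], truths[0].replicase[0])
    table = orf_table(record)
    assert table.startswith("id\tstart\tend")
    assert "\tmaturation\t" in table and "\treplicase\t" in table
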