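import pandas as pd
import pytest
from pyfaidx import Fasta

from mirparc.seedscan import (
    build_gene_models,
    classify_match_regions,
    extract_seed,
    find_seed,
    gene_sequence,
    longest_transcript,
    read_mirna_fasta,
    summarize_seed_presence,
    to_genomic,
    to_transcript,
)

from conftest import IMPLANT_PLAN


def test_seed_extraction_positions_2_to_8():
    assert extract_seed("ACGUACGUACGU") == "CGUACGU"
    assert extract_seed("ACGUACGU") == "CGUACGU"       # 8-nt: last 7 bases
    assert extract_seed("acgtacgtacgt") == "CGUACGU"   # case + T->U normalization
    with pytest.raises(ValueError):
        extract_seed("ACGUACG")                         # 7 nt: too short


def test_find_seed_orientations():
    # reverse complement of seed ACGUACG is CGTACGT
    assert find_seed("AAACGTACGTAAA", "ACGUACG") == [4]
    assert find_seed("ACGTACG", "ACGUACG", match_mode="literal") == [1]
    assert find_seed("AAAAAAAAA", "CCCCCCC") == []
    # overlapping hits are all reported
    assert find_seed("ATATATATATA", "UAUAUAU", match_mode="literal") == [2, 4]


def test_plus_and_minus_strand_gene_sequence(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c1\nAAACGTTT\n")
    from mirparc.seedscan import GeneModel

    # 1-based inclusive span 4..7 of AAACGTTT
    plus = GeneModel("g+", "c1", "+", 1, 8, "t", 4, 7)
    minus = GeneModel("g-", "c1", "-", 1, 8, "t", 4, 7)
    genome = Fasta(str(fa))
    assert gene_sequence(plus, genome) == "CGTT"
    assert gene_sequence(minus, genome) == "AACG"
    with pytest.raises(ValueError):
        gene_sequence(GeneModel("g", "c1", "+", 1, 99, "t", 1, 99), genome)


def test_longest_transcript_rule_and_intervals(toy_genome):
    models = build_gene_models(toy_genome.gtf)
    for gid, seed, region in IMPLANT_PLAN:
        m = longest_transcript(models, gid)
        assert m.longest_transcript_id == f"{gid}.T1"
        span = m.tx_end - m.tx_start + 1
        assert span == 600
        assert len(m.cds) == 2 and len(m.five_utr) == 1 and len(m.three_utr) == 1
    with pytest.raises(KeyError):
        longest_transcript(models, "NOSUCHGENE")


def test_coordinate_round_trip_identity_both_strands(toy_genome):
    models = build_gene_models(toy_genome.gtf)
    strands = {m.strand for m in models.values()}
    assert strands == {"+", "-"}
    for m in models.values():
        for pos in (1, 17, 300, 594):
            assert to_transcript(m, to_genomic(m, pos)) == pos


def test_implanted_seeds_found_in_planned_regions(toy_genome):
    models = build_gene_models(toy_genome.gtf)
    genome = Fasta(str(toy_genome.genome_fasta))
    seqs = read_mirna_fasta(toy_genome.mirna_fasta)
    for _, row in toy_genome.plan.iterrows():
        m = models[row["gene"]]
        seed = extract_seed(seqs[row["mirna"]])
        assert seed == row["seed"]
        hits = find_seed(gene_sequence(m, genome), seed)
        flags = classify_match_regions(m, hits)
        if row["region"] == "shorter_exon":
            assert hits == []
        else:
            assert len(hits) == 1
            expected = {"5putr": "five_utr", "cds": "cds", "3putr": "three_utr"}
            for reg, flag in expected.items():
                assert flags[flag] == (row["region"] == reg)
            assert flags["anywhere"]


def test_seed_presence_summary_percentages(toy_genome):
    models = build_gene_models(toy_genome.gtf)
    seqs = read_mirna_fasta(toy_genome.mirna_fasta)
    table = toy_genome.plan.rename(columns={})[["gene", "mirna"]]
    summary, detail = summarize_seed_presence(
        table, models, toy_genome.genome_fasta, seqs
    )
    # 10 implants: 8 findable (2 shorter_exon excluded by the longest-transcript
    # rule), 2 per annotated region, 2 intronic
    assert summary.n_interactions == 10
    assert summary.with_seed_anywhere == 80.0
    assert summary.in_5putr == 20.0
    assert summary.in_3putr == 20.0
    assert summary.in_cds == 20.0
    assert summary.in_any_annotated_region == 60.0
    assert summary.in_any_annotated_region <= (
        summary.in_5putr + summary.in_3putr + summary.in_cds
    )
    assert summary.with_seed_anywhere >= max(
        summary.in_5putr, summary.in_3putr, summary.in_cds
    )

    missing = pd.DataFrame({"gene": ["NOPE"], "mirna": ["mir-1"]})
    none_summary, empty_detail = summarize_seed_presence(
        missing, models, toy_genome.genome_fasta, seqs
    )
    assert none_summary is None and empty_detail.empty


def test_utrs_derived_when_gtf_lacks_utr_lines(toy_genome, tmp_path):
    lines = [
        l for l in toy_genome.gtf.read_text().splitlines()
        if "\tfive_prime_utr\t" not in l and "\tthree_prime_utr\t" not in l
    ]
    bare = tmp_path / "bare.gtf"
    bare.write_text("\n".join(lines) + "\n")
    explicit = build_gene_models(toy_genome.gtf)
    derived = build_gene_models(bare)
    for gid in explicit:
        assert derived[gid].five_utr == explicit[gid].five_utr
        assert derived[gid].three_utr == explicit[gid].three_utr
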