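"""Seed-region analysis of selected interactions.

The miRNA seed (bases 2-8 from the 5' end, 7 nt) is searched by exact
match in each target gene's sequence, where the gene sequence is the
unspliced genomic span of its longest transcript (introns included),
read 5'->3' in transcript orientation.  Matches are attributed to the
longest transcript's 5'UTR / CDS / 3'UTR intervals; one interaction may
hit several regions.  All genomic coordinates are 1-based inclusive
(GTF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

SEED_LENGTH = 7

Interval = tuple[int, int]  # 1-based inclusive genomic


@dataclass
class GeneModel:
    """Longest-transcript gene model for seed scanning and chromosomal ordering."""

    gene_id: str
    chromosome: str
    strand: str
    gene_start: int
    gene_end: int
    longest_transcript_id: str
    tx_start: int
    tx_end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    five_utr: list[Interval] = field(default_factory=list)
    three_utr: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.gene_id}: gene_start > gene_end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def extract_seed(mirna_seq: str, start: int = 2, end: int = 8) -> str:
    """Seed of a mature miRNA: bases ``start``..``end`` (1-based, 5' end first).

    T is accepted and normalized to U; default positions 2-8 give 7 nt.
    """
    seq = mirna_seq.strip().upper().replace("T", "U")
    if len(seq) < end:
        raise ValueError(f"miRNA sequence shorter than {end} nt")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"unexpected bases in miRNA sequence: {sorted(bad)}")
    return seq[start - 1 : end]


def _intervals(db: gffutils.FeatureDB, tx_id: str, featuretype: str) -> list[Interval]:
    return sorted(
        (f.start, f.end)
        for f in db.children(tx_id, featuretype=featuretype)
    )


def _derive_utrs(
    exons: list[Interval], cds: list[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Exonic regions outside the CDS span, split into 5' and 3' by strand.

    Used for GTF dialects without explicit UTR feature lines.
    """
    if not cds:
        return [], []
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    upstream: list[Interval] = []    # genomically left of the CDS span
    downstream: list[Interval] = []  # genomically right
    for s, e in exons:
        if s < cds_lo:
            upstream.append((s, min(e, cds_lo - 1)))
        if e > cds_hi:
            downstream.append((max(s, cds_hi + 1), e))
    if strand == "+":
        return upstream, downstream
    return downstream, upstream


def build_gene_models(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF into per-gene longest-transcript models.

    The longest transcript maximizes genomic span (end - start + 1); ties
    break on transcript ID (lexicographic).  When the GTF has no UTR lines,
    UTRs are derived as exonic sequence outside the CDS span.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene.id, featuretype="transcript"))
        if not transcripts:
            logger.warning("%s: no transcripts in GTF; skipped", gene.id)
            continue
        # widest genomic span wins; ties break to the smallest transcript ID
        best = min(transcripts, key=lambda t: (-(t.end - t.start + 1), t.id))
        exons = _intervals(db, best.id, "exon")
        cds = _intervals(db, best.id, "CDS")
        five = _intervals(db, best.id, "five_prime_utr") + _intervals(db, best.id, "5UTR")
        three = _intervals(db, best.id, "three_prime_utr") + _intervals(db, best.id, "3UTR")
        if not five and not three and cds:
            five, three = _derive_utrs(exons, cds, gene.strand)
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            gene_start=gene.start,
            gene_end=gene.end,
            longest_transcript_id=best.id,
            tx_start=best.start,
            tx_end=best.end,
            exons=exons,
            cds=cds,
            five_utr=sorted(five),
            three_utr=sorted(three),
        )
    return models


def longest_transcript(models: dict[str, GeneModel], gene_id: str) -> GeneModel:
    """Model for one gene; raises ``KeyError`` when the gene is absent from the GTF."""
    if gene_id not in models:
        raise KeyError(f"gene {gene_id!r} not present in the annotation")
    return models[gene_id]


def gene_sequence(model: GeneModel, genome: Fasta | str | Path) -> str:
    """Unspliced longest-transcript span, 5'->3' in transcript orientation.

    Minus-strand genes are reverse-complemented so the returned DNA string
    reads in the same direction the mature mRNA would.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    if model.chromosome not in genome:
        raise KeyError(f"chromosome {model.chromosome!r} absent from FASTA")
    chrom_len = len(genome[model.chromosome])
    if model.tx_end > chrom_len or model.tx_start < 1:
        raise ValueError(
            f"{model.gene_id}: span {model.tx_start}-{model.tx_end} exceeds "
            f"chromosome length {chrom_len}"
        )
    seq = genome[model.chromosome][model.tx_start - 1 : model.tx_end].seq.upper()
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def find_seed(
    gene_seq: str, seed: str, match_mode: str = "reverse_complement"
) -> list[int]:
    """All (overlapping) exact seed matches, 1-based transcript-oriented starts.

    ``reverse_complement`` (default) searches the DNA reverse complement of
    the seed — the sense a target site has, since the miRNA pairs
    antiparallel to the mRNA.  ``literal`` searches the seed with U->T.
    """
    if len(seed) != SEED_LENGTH:
        raise ValueError(f"seed must be {SEED_LENGTH} nt")
    if match_mode == "reverse_complement":
        query = str(Seq(seed.replace("U", "T")).reverse_complement())
    elif match_mode == "literal":
        query = seed.replace("U", "T")
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    hits = []
    pos = gene_seq.find(query)
    while pos != -1:
        hits.append(pos + 1)
        pos = gene_seq.find(query, pos + 1)
    return hits


def to_genomic(model: GeneModel, position: int, length: int = SEED_LENGTH) -> Interval:
    """Transcript-oriented 1-based start -> genomic 1-based inclusive interval."""
    if model.strand == "+":
        g = model.tx_start + position - 1
        return g, g + length - 1
    g_end = model.tx_end - position + 1
    return g_end - length + 1, g_end


def to_transcript(model: GeneModel, interval: Interval) -> int:
    """Genomic interval -> transcript-oriented 1-based start (round-trip of ``to_genomic``)."""
    lo, hi = interval
    if model.strand == "+":
        return lo - model.tx_start + 1
    return model.tx_end - hi + 1


def _overlaps(iv: Interval, regions: list[Interval]) -> bool:
    lo, hi = iv
    return any(lo <= e and hi >= s for s, e in regions)


def classify_match_regions(
    model: GeneModel, positions: list[int]
) -> dict[str, bool]:
    """Flag whether any match overlaps the 5'UTR, 3'UTR or CDS of the model.

    A single interaction may set several flags (a seed can recur across
    regions); matches in introns set only ``anywhere``.
    """
    flags = {"anywhere": bool(positions), "five_utr": False, "three_utr": False, "cds": False}
    for pos in positions:
        iv = to_genomic(model, pos)
        flags["five_utr"] |= _overlaps(iv, model.five_utr)
        flags["three_utr"] |= _overlaps(iv, model.three_utr)
        flags["cds"] |= _overlaps(iv, model.cds)
    return flags


@dataclass(frozen=True)
class SeedMatchSummary:
    """Percentages of interactions (with sequences available) carrying the seed."""

    n_interactions: int
    with_seed_anywhere: float
    in_5putr: float
    in_3putr: float
    in_cds: float
    in_any_annotated_region: float

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "Perc. with seed region": self.with_seed_anywhere,
            "Perc. seed region in 5pUTR": self.in_5putr,
            "Perc. seed region in 3pUTR": self.in_3putr,
            "Perc. seed region in coding region": self.in_cds,
            "Perc. seed region in 5pUTR or 3pUTR or coding region": self.in_any_annotated_region,
        }
        return pd.DataFrame({"percent": rows})


def summarize_seed_presence(
    table: pd.DataFrame,
    models: dict[str, GeneModel],
    genome: Fasta | str | Path,
    mirna_seqs: dict[str, str],
    match_mode: str = "reverse_complement",
) -> tuple[SeedMatchSummary | None, pd.DataFrame]:
    """Seed-presence percentages over an interaction table, plus per-row detail.

    Interactions whose gene model or miRNA sequence is unavailable are
    logged and excluded from the denominators.  Returns ``(None, empty)``
    for an empty usable set.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    records = []
    skipped = 0
    seq_cache: dict[str, str] = {}
    for gene, mirna in zip(table["gene"], table["mirna"]):
        if gene not in models or mirna not in mirna_seqs:
            skipped += 1
            continue
        model = models[gene]
        if gene not in seq_cache:
            seq_cache[gene] = gene_sequence(model, genome)
        seed = extract_seed(mirna_seqs[mirna])
        hits = find_seed(seq_cache[gene], seed, match_mode)
        flags = classify_match_regions(model, hits)
        records.append(
            {
                "gene": gene,
                "mirna": mirna,
                "n_matches": len(hits),
                "anywhere": flags["anywhere"],
                "in_5putr": flags["five_utr"],
                "in_3putr": flags["three_utr"],
                "in_cds": flags["cds"],
                "in_any_region": flags["five_utr"] or flags["three_utr"] or flags["cds"],
            }
        )
    if skipped:
        logger.warning("seedscan: %d interactions lacked a model or miRNA sequence", skipped)
    detail = pd.DataFrame(records)
    if detail.empty:
        logger.warning("seedscan: no interactions with available sequences")
        return None, detail
    pct = lambda col: 100.0 * detail[col].mean()
    summary = SeedMatchSummary(
        n_interactions=len(detail),
        with_seed_anywhere=pct("anywhere"),
        in_5putr=pct("in_5putr"),
        in_3putr=pct("in_3putr"),
        in_cds=pct("in_cds"),
        in_any_annotated_region=pct("in_any_region"),
    )
    return summary, detail


def read_mirna_fasta(path: str | Path) -> dict[str, str]:
    """Mature miRNA sequences keyed by FASTA record ID (first token)."""
    seqs: dict[str, str] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = ""
            elif current is not None:
                seqs[current] += line
    return seqs
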