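"""Metagenomic fragment recruitment and RPKG abundance estimates.

A read is recruited to a (rRNA-masked) genome when its best local
alignment has aligned length >= 50 bp, identity >= 95% and e-value
<= 1e-5; each read counts at most once per genome, and hits overlapping
masked blocks by more than half of the alignment are discarded.
RPKG = reads recruited per kb of genome per Gb of metagenome, a
size-normalised abundance comparable across genomes and metagenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from genostream.align import ScoringScheme
from genostream.identity import align_in_window, kmer_index
from genostream.io import GenomeRecord


class UnmaskedGenomeError(ValueError):
    """Recruitment against a genome whose rRNA loci were not masked."""


@dataclass
class ReadSet:
    """One metagenome: reads, total bp and an ecosystem tag."""

    metagenome_id: str
    reads: list[tuple[str, str]]
    ecosystem: str = "other"

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids in {self.metagenome_id!r}")
        if self.total_bp <= 0:
            raise ValueError(f"metagenome {self.metagenome_id!r} has zero bp")

    @property
    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class RecruitmentResult:
    genome_id: str
    metagenome_id: str
    reads_recruited: int
    hits: pd.DataFrame = field(repr=False, default=None)


def read_set_from_fastx(path, metagenome_id: str | None = None,
                        ecosystem: str = "other") -> ReadSet:
    """Load reads from FASTA/FASTQ (optionally gzipped)."""
    import gzip
    from pathlib import Path

    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name.removesuffix(".gz")
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    return ReadSet(metagenome_id or path.stem, reads, ecosystem)


def _masked_overlap(start: int, end: int, blocks) -> int:
    return sum(max(0, min(end, e) - max(start, s)) for s, e in blocks)


def recruit(reads: ReadSet, genome: GenomeRecord, *, min_length: int = 50,
            min_identity: float = 95.0, max_evalue: float = 1e-5,
            k: int = 13, waive_masking: bool = False,
            scheme: ScoringScheme | None = None) -> RecruitmentResult:
    """Count reads whose best alignment to the genome passes all cutoffs.

    The genome must carry ``metadata['rrna_masked']`` (see
    :func:`genostream.io.mask_rrna`) unless masking is explicitly waived
    or the genome has no annotated rRNA.
    """
    has_rrna = bool(genome.features_of_type("rRNA"))
    if has_rrna and not genome.metadata.get("rrna_masked") and not waive_masking:
        raise UnmaskedGenomeError(
            f"genome {genome.genome_id!r} has annotated rRNA but was not "
            "masked; run genostream.io.mask_rrna(genome) first or pass "
            "waive_masking=True")
    scheme = scheme or ScoringScheme.nucleotide_default()
    subjects = {r.id: r.sequence for r in genome.replicons}
    idx = kmer_index(subjects, k)
    masked = genome.metadata.get("masked_intervals", {})
    genome_len = genome.genome_size
    rows = []
    for rid, seq in reads.reads:
        hit = align_in_window(seq, subjects, idx, k, step=4, margin=24)
        if hit is None or hit["columns"] < min_length:
            continue
        ident = 100.0 * hit["matches"] / hit["columns"]
        if ident < min_identity:
            continue
        # raw score under the nucleotide scheme, gaps charged per run
        gap_cols = hit["columns"] - hit["matches"] - hit["mismatches"]
        raw = (scheme.match * hit["matches"] + scheme.mismatch * hit["mismatches"]
               - hit["gap_runs"] * scheme.gap_open - gap_cols * scheme.gap_extend)
        evalue = scheme.evalue(raw, len(seq), genome_len)
        if evalue > max_evalue:
            continue
        blocks = masked.get(hit["sid"], ())
        if blocks and _masked_overlap(hit["start"], hit["end"], blocks) \
                > 0.5 * hit["columns"]:
            continue
        rows.append((rid, hit["sid"], hit["start"], hit["end"], hit["strand"],
                     hit["columns"], ident, evalue))
    hits = pd.DataFrame(rows, columns=["read_id", "replicon_id", "start", "end",
                                       "strand", "alen", "pident", "evalue"])
    return RecruitmentResult(genome.genome_id, reads.metagenome_id,
                             len(hits), hits)


def rpkg(reads_recruited: int, genome_size_bp: int,
         metagenome_total_bp: int) -> float:
    """Reads per kb of genome per Gb of metagenome."""
    if genome_size_bp <= 0 or metagenome_total_bp <= 0:
        raise ValueError("genome and metagenome sizes must be positive")
    return reads_recruited / ((genome_size_bp / 1e3) * (metagenome_total_bp / 1e9))


def rpkg_table(results, genomes, read_sets) -> pd.DataFrame:
    """RPKG rows from recruitment results.

    ``genomes``/``read_sets`` provide sizes and ecosystem tags by id.
    """
    gsize = {g.genome_id: g.genome_size for g in genomes}
    msize = {m.metagenome_id: m.total_bp for m in read_sets}
    eco = {m.metagenome_id: m.ecosystem for m in read_sets}
    rows = []
    for r in results:
        rows.append({
            "genome_id": r.genome_id, "metagenome_id": r.metagenome_id,
            "ecosystem": eco[r.metagenome_id],
            "reads_recruited": r.reads_recruited,
            "genome_kb": gsize[r.genome_id] / 1e3,
            "metagenome_gb": msize[r.metagenome_id] / 1e9,
            "rpkg": rpkg(r.reads_recruited, gsize[r.genome_id],
                         msize[r.metagenome_id]),
        })
    return pd.DataFrame(rows)


def summarize_by_ecosystem(table: pd.DataFrame) -> pd.DataFrame:
    """Maximum RPKG per (genome, ecosystem); ties resolved stably."""
    if "ecosystem" not in table.columns:
        raise ValueError("RPKG table lacks ecosystem tags")
    idx = table.groupby(["genome_id", "ecosystem"], sort=True)["rpkg"].idxmax()
    out = table.loc[idx, ["genome_id", "ecosystem", "metagenome_id", "rpkg"]]
    return out.reset_index(drop=True)
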