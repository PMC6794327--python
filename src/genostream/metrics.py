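"""Per-genome streamlining indicators.

Genome-streamlined oligotrophs show small genomes, low GC, compact
intergenic spacers, high coding density, few paralogs and regulators,
TAA-over-TAG stop-codon bias, lysine-over-arginine usage and proteomes
economical in nitrogen and sulfur.  This module computes that indicator
suite for one annotated genome; the paralog count is injected from
:mod:`genostream.pangenome` so each quantity has a single owner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

from genostream.io import (
    GenomeRecord,
    GenomeValidationError,
    ProteinSet,
    merge_intervals,
)

GENE_FTYPES = ("CDS", "rRNA", "tRNA")

STOP_CODONS = ("TAA", "TAG", "TGA")

# residue formulas: free amino acid minus one water -> (C, H, N, O, S)
RESIDUE_ATOMS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

DEFAULT_CLASS_PATTERNS = {
    "histidine_kinase": (r"histidine kinase",),
    "sigma_factor": (r"sigma factor", r"sigma-70", r"rna polymerase sigma"),
}


@dataclass
class StreamliningProfile:
    """The per-genome metric vector behind the streamlining indicator panels."""

    genome_id: str
    genome_size_bp: int
    gc_percent: float
    mean_igs_bp: float
    coding_density_percent: float
    mean_cds_bp: float
    overlapping_cds_percent: float
    n_paralogs: int
    n_histidine_kinases: int
    n_sigma_factors: int
    stop_taa_percent: float
    stop_tag_percent: float
    stop_tga_percent: float
    lys_percent: float
    arg_percent: float
    c_per_aa: float
    n_per_aa: float
    s_per_aa: float
    c_molpercent: float
    n_molpercent: float
    s_molpercent: float

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class IncompleteProfileError(ValueError):
    """A profile component is missing or empty."""


# ---------------------------------------------------------------------------
# sequence composition


def gc_content(genome: GenomeRecord) -> float:
    """GC% over unambiguous nucleotides; N excluded from both sides."""
    gc = at = 0
    for rep in genome.replicons:
        s = rep.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise GenomeValidationError(
            f"genome {genome.genome_id!r}: no unambiguous nucleotides")
    return 100.0 * gc / (gc + at)


# ---------------------------------------------------------------------------
# architecture


def _logical_intervals(genome: GenomeRecord, ftypes) -> dict[str, list[tuple[int, int, str]]]:
    """Per replicon: (start, end, logical_id), origin-spanning parts kept as parts."""
    out: dict[str, list[tuple[int, int, str]]] = {r.id: [] for r in genome.replicons}
    for f in genome.features:
        if f.ftype in ftypes:
            out[f.replicon_id].append((f.start, f.end, f.logical_id))
    return out


def intergenic_spacers(genome: GenomeRecord) -> list[int]:
    """Strand-agnostic gaps between consecutive annotated gene features.

    Overlapping neighbours contribute a spacer of 0; circular replicons
    include the wrap-around gap.  Parts of one origin-spanning feature do
    not generate a spacer between themselves.
    """
    spacers: list[int] = []
    by_id = genome.replicons_by_id()
    for rid, ivs in _logical_intervals(genome, GENE_FTYPES).items():
        if not ivs:
            continue
        rep = by_id[rid]
        ivs = sorted(ivs)
        n = len(ivs)
        if n == 1:
            if rep.circular:
                spacers.append(len(rep) - (ivs[0][1] - ivs[0][0]))
            continue
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if id1 == id2:
                continue
            spacers.append(max(0, s2 - e1))
        if rep.circular:
            first, last = ivs[0], ivs[-1]
            if first[2] != last[2]:
                spacers.append(max(0, len(rep) - last[1] + first[0]))
    return spacers


def coding_density(genome: GenomeRecord) -> float:
    """Percent of the genome covered by the union of CDS intervals."""
    covered = 0
    for rid, ivs in _logical_intervals(genome, ("CDS",)).items():
        covered += sum(e - s for s, e in merge_intervals((s, e) for s, e, _ in ivs))
    return 100.0 * covered / genome.genome_size


def cds_length_stats(genome: GenomeRecord) -> tuple[float, float]:
    """(mean CDS nucleotide length, % of CDS overlapping >=1 bp with another CDS)."""
    lengths: dict[str, int] = {}
    per_rep = _logical_intervals(genome, ("CDS",))
    for ivs in per_rep.values():
        for s, e, lid in ivs:
            lengths[lid] = lengths.get(lid, 0) + (e - s)
    if not lengths:
        raise GenomeValidationError(f"genome {genome.genome_id!r} has no CDS")
    overlapping: set[str] = set()
    for ivs in per_rep.values():
        ivs = sorted(ivs)
        active: list[tuple[int, str]] = []  # (end, logical_id)
        for s, e, lid in ivs:
            active = [(ae, al) for ae, al in active if ae > s]
            for ae, al in active:
                if al != lid:
                    overlapping.add(al)
                    overlapping.add(lid)
            active.append((e, lid))
    mean_len = sum(lengths.values()) / len(lengths)
    return mean_len, 100.0 * len(overlapping) / len(lengths)


# ---------------------------------------------------------------------------
# codon / residue usage


def stop_codon_usage(genome: GenomeRecord) -> tuple[float, float, float, int]:
    """(TAA%, TAG%, TGA%, n_noncanonical) over CDS terminal codons.

    Percentages are over CDS ending in a canonical stop on their coding
    strand; CDS lacking one are excluded and counted separately.
    """
    counts = {c: 0 for c in STOP_CODONS}
    noncanonical = 0
    seen: set[str] = set()
    for f in genome.features_of_type("CDS"):
        if f.logical_id in seen:
            continue
        seen.add(f.logical_id)
        nt = genome.cds_nt_sequence(f.logical_id)
        stop = nt[-3:]
        if stop in counts:
            counts[stop] += 1
        else:
            noncanonical += 1
    total = sum(counts.values())
    if total == 0:
        return 0.0, 0.0, 0.0, noncanonical
    return (100.0 * counts["TAA"] / total, 100.0 * counts["TAG"] / total,
            100.0 * counts["TGA"] / total, noncanonical)


def aa_usage(proteins: ProteinSet) -> dict[str, float]:
    """Percent of proteome residues per amino acid; X excluded from both sides."""
    counts = {aa: 0 for aa in RESIDUE_ATOMS}
    for _, seq in proteins:
        for aa in seq:
            if aa in counts:
                counts[aa] += 1
    total = sum(counts.values())
    if total == 0:
        raise GenomeValidationError(
            f"proteome {proteins.genome_id!r} has no unambiguous residues")
    return {aa: 100.0 * c / total for aa, c in counts.items()}


def atom_composition(proteins: ProteinSet) -> dict[str, float]:
    """Mean C/N/S atoms per residue and element mol% of the whole proteome.

    Atoms per residue uses the residue formula (free amino acid minus one
    water); mol% is the element's share of all C+H+N+O+S atoms.
    """
    totals = [0, 0, 0, 0, 0]  # C H N O S
    nres = 0
    for pid, seq in proteins:
        for aa in seq:
            if aa == "X":
                continue
            if aa not in RESIDUE_ATOMS:
                raise GenomeValidationError(
                    f"protein {pid!r}: unknown residue letter {aa!r}")
            for i, v in enumerate(RESIDUE_ATOMS[aa]):
                totals[i] += v
            nres += 1
    if nres == 0:
        raise GenomeValidationError(
            f"proteome {proteins.genome_id!r} has no unambiguous residues")
    c, h, n, o, s = totals
    allatoms = sum(totals)
    return {
        "c_per_aa": c / nres, "n_per_aa": n / nres, "s_per_aa": s / nres,
        "c_molpercent": 100.0 * c / allatoms,
        "n_molpercent": 100.0 * n / allatoms,
        "s_molpercent": 100.0 * s / allatoms,
    }


def count_annotation_class(genome: GenomeRecord, class_patterns) -> int:
    """CDS whose product label matches any pattern (case-insensitive regex)."""
    patterns = list(class_patterns)
    if not patterns:
        raise ValueError("empty pattern set")
    regs = [re.compile(p, re.IGNORECASE) for p in patterns]
    seen: set[str] = set()
    n = 0
    for f in genome.features_of_type("CDS"):
        if f.logical_id in seen:
            continue
        seen.add(f.logical_id)
        if any(r.search(f.product or "") for r in regs):
            n += 1
    return n


# ---------------------------------------------------------------------------
# aggregation


def streamlining_profile(genome: GenomeRecord, proteins: ProteinSet,
                         paralog_count: int,
                         class_patterns: dict | None = None,
                         ) -> StreamliningProfile:
    """Assemble the full indicator vector for one genome."""
    if proteins.genome_id != genome.genome_id:
        raise IncompleteProfileError(
            f"proteome genome_id {proteins.genome_id!r} does not match "
            f"genome {genome.genome_id!r}")
    if len(proteins) == 0:
        raise IncompleteProfileError(f"empty proteome for {genome.genome_id!r}")
    patterns = class_patterns or DEFAULT_CLASS_PATTERNS
    spacers = intergenic_spacers(genome)
    mean_cds, pct_overlap = cds_length_stats(genome)
    taa, tag, tga, _ = stop_codon_usage(genome)
    usage = aa_usage(proteins)
    atoms = atom_composition(proteins)
    return StreamliningProfile(
        genome_id=genome.genome_id,
        genome_size_bp=genome.genome_size,
        gc_percent=gc_content(genome),
        mean_igs_bp=(sum(spacers) / len(spacers)) if spacers else 0.0,
        coding_density_percent=coding_density(genome),
        mean_cds_bp=mean_cds,
        overlapping_cds_percent=pct_overlap,
        n_paralogs=paralog_count,
        n_histidine_kinases=count_annotation_class(
            genome, patterns["histidine_kinase"]),
        n_sigma_factors=count_annotation_class(genome, patterns["sigma_factor"]),
        stop_taa_percent=taa, stop_tag_percent=tag, stop_tga_percent=tga,
        lys_percent=usage["K"], arg_percent=usage["R"],
        **atoms,
    )


def profiles_to_tsv(path, profiles) -> None:
    import pandas as pd

    pd.DataFrame([p.to_row() for p in profiles]).to_csv(path, sep="\t", index=False)


def profiles_from_tsv(path) -> list[StreamliningProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [StreamliningProfile(**row) for row in df.to_dict("records")]
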