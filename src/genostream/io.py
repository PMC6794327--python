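"""Annotated-genome I/O and the canonical in-memory data model.

Coordinates are 0-based half-open on the forward strand throughout the
package; GFF3 (1-based inclusive) and GenBank conversions happen at the
boundary.  A feature that spans the origin of a circular replicon is
stored as two :class:`Feature` parts sharing one ``logical_id``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_NUC = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class GenomeFormatError(ValueError):
    """Malformed or inconsistent input annotation/sequence."""


class GenomeValidationError(ValueError):
    """Structurally valid input violating a model invariant."""


def _normalize_nt(seq: str, context: str = "") -> str:
    """Upper-case and collapse non-ACGT ambiguity codes to N (logged)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _NUC
    if bad:
        log.info("normalized %d ambiguity code(s) %s to N%s",
                 sum(s.count(b) for b in bad), sorted(bad),
                 f" in {context}" if context else "")
        s = "".join(c if c in _NUC else "N" for c in s)
    return s


@dataclass
class Replicon:
    """One contig/chromosome: id, normalized sequence, circularity flag."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = _normalize_nt(self.sequence, self.id)
        if len(self.sequence) == 0:
            raise GenomeValidationError(f"replicon {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """An annotated interval on a replicon (0-based half-open, forward strand).

    ``logical_id`` groups the two parts of an origin-spanning feature on a
    circular replicon; for ordinary features it equals ``feature_id``.
    """

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    ftype: str  # CDS, rRNA, tRNA, other
    product: str = ""
    protein: str | None = None
    partial: bool = False
    logical_id: str = ""

    def __post_init__(self) -> None:
        if not self.logical_id:
            self.logical_id = self.feature_id
        if self.strand not in "+-":
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"feature {self.feature_id!r}: bad interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """Replicon sequences plus CDS/rRNA/tRNA features for one genome."""

    genome_id: str
    replicons: list[Replicon]
    features: list[Feature]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_id = self.replicons_by_id()
        for f in self.features:
            rep = by_id.get(f.replicon_id)
            if rep is None:
                raise GenomeFormatError(
                    f"feature {f.feature_id!r} references unknown replicon "
                    f"{f.replicon_id!r}")
            if f.end > len(rep):
                raise GenomeValidationError(
                    f"feature {f.feature_id!r} [{f.start},{f.end}) exceeds "
                    f"replicon {rep.id!r} length {len(rep)}")
        if self.genome_size <= 0:
            raise GenomeValidationError("genome has zero size")

    def replicons_by_id(self) -> dict[str, Replicon]:
        return {r.id: r for r in self.replicons}

    @property
    def genome_size(self) -> int:
        return sum(len(r) for r in self.replicons)

    def features_of_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self.features if f.ftype in ftypes]

    def cds_nt_sequence(self, logical_id: str) -> str:
        """Coding-strand nucleotide sequence of one logical CDS.

        Parts of an origin-spanning CDS are concatenated in forward-strand
        order before reverse complementing.
        """
        parts = [f for f in self.features if f.logical_id == logical_id]
        if not parts:
            raise KeyError(logical_id)
        strand = parts[0].strand
        rep = self.replicons_by_id()[parts[0].replicon_id]
        if len(parts) > 1:
            # origin-spanning: the part touching the right end comes first
            parts = sorted(parts, key=lambda f: f.start, reverse=True)
        seq = "".join(rep.sequence[f.start:f.end] for f in parts)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class ProteinSet:
    """Proteome of one genome: unique ids over the 20-letter alphabet + X."""

    genome_id: str
    proteins: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.proteins]
        if len(ids) != len(set(ids)):
            raise GenomeValidationError(
                f"duplicate protein ids in proteome {self.genome_id!r}")
        for pid, seq in self.proteins:
            if not seq or set(seq) - _AA:
                raise GenomeValidationError(
                    f"protein {pid!r}: empty or non-amino-acid letters "
                    f"{sorted(set(seq) - _AA)}")

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def as_dict(self) -> dict[str, str]:
        return dict(self.proteins)


# ---------------------------------------------------------------------------
# loading


def _features_from_gff3(path, replicons: dict[str, Replicon]) -> list[Feature]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    feats: list[Feature] = []
    keep = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
    n_auto = 0
    for rec in db.all_features():
        ftype = keep.get(rec.featuretype)
        if ftype is None:
            continue
        if rec.seqid not in replicons:
            raise GenomeFormatError(
                f"GFF3 feature {rec.id!r} on unknown seqid {rec.seqid!r}")
        attrs = rec.attributes
        fid = attrs.get("ID", [None])[0]
        if fid is None:
            n_auto += 1
            fid = f"{rec.seqid}_{ftype}_{n_auto}"
        product = attrs.get("product", [""])[0]
        partial = "partial" in attrs or attrs.get("pseudo") is not None
        protein = attrs.get("translation", [None])[0]
        feats.append(Feature(
            feature_id=fid, replicon_id=rec.seqid,
            start=rec.start - 1, end=rec.end,  # GFF3 is 1-based inclusive
            strand=rec.strand if rec.strand in "+-" else "+",
            ftype=ftype, product=product, protein=protein, partial=partial,
        ))
    return feats


def _features_from_genbank(records) -> tuple[list[Replicon], list[Feature], dict]:
    replicons, feats, meta = [], [], {}
    keep = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
    for rec in records:
        circular = rec.annotations.get("topology", "circular") == "circular"
        replicons.append(Replicon(rec.id, str(rec.seq), circular=circular))
        meta.setdefault("source", rec.annotations.get("source", ""))
        for i, f in enumerate(rec.features):
            ftype = keep.get(f.type)
            if ftype is None:
                continue
            q = f.qualifiers
            fid = q.get("locus_tag", q.get("protein_id", [f"{rec.id}_{f.type}_{i}"]))[0]
            feats.append(Feature(
                feature_id=fid, replicon_id=rec.id,
                start=int(f.location.start), end=int(f.location.end),
                strand="-" if f.location.strand == -1 else "+",
                ftype=ftype, product=q.get("product", [""])[0],
                protein=q.get("translation", [None])[0],
                partial="<" in str(f.location) or ">" in str(f.location),
            ))
    return replicons, feats, meta


def load_genome(sequence_path=None, annotation_path=None, *,
                circular_default: bool = True, genome_id: str | None = None,
                ) -> GenomeRecord:
    """Load a genome from FASTA + GFF3, or from a GenBank flat file.

    ``load_genome(fasta, gff3)`` reads sequences and features separately;
    ``load_genome(annotation_path=gbk)`` (or a single ``.gb``/``.gbk``/
    ``.gbff`` path) takes both from the GenBank record.  GFF3 seqids must
    match FASTA headers on the first whitespace-delimited token.
    """
    if sequence_path is not None and str(sequence_path).lower().endswith(
            (".gb", ".gbk", ".gbff", ".genbank")) and annotation_path is None:
        sequence_path, annotation_path = None, sequence_path
    if sequence_path is None:
        records = list(SeqIO.parse(str(annotation_path), "genbank"))
        if not records:
            raise GenomeFormatError(f"no GenBank records in {annotation_path}")
        replicons, feats, meta = _features_from_genbank(records)
        gid = genome_id or records[0].id
        return GenomeRecord(gid, replicons, feats, meta)

    replicons = [
        Replicon(rec.id, str(rec.seq), circular=circular_default)
        for rec in SeqIO.parse(str(sequence_path), "fasta")
    ]
    if not replicons:
        raise GenomeFormatError(f"no FASTA records in {sequence_path}")
    by_id = {r.id: r for r in replicons}
    feats = _features_from_gff3(annotation_path, by_id) if annotation_path else []
    gid = genome_id or replicons[0].id
    return GenomeRecord(gid, replicons, feats)


# ---------------------------------------------------------------------------
# protein extraction

_BACTERIAL_TABLE = 11


def extract_proteins(genome: GenomeRecord) -> ProteinSet:
    """One protein per logical CDS; annotation translation preferred.

    CDS without an annotated translation are translated with the bacterial
    genetic code; a trailing stop is stripped; CDS whose translation has an
    internal stop are excluded with a warning.
    """
    cds = genome.features_of_type("CDS")
    if not cds:
        raise GenomeValidationError(f"genome {genome.genome_id!r} has no CDS")
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for f in cds:
        if f.logical_id in seen:
            continue
        seen.add(f.logical_id)
        if f.protein:
            aa = f.protein.rstrip("*")
        else:
            nt = genome.cds_nt_sequence(f.logical_id)
            if len(nt) % 3 and not f.partial:
                warnings.warn(
                    f"CDS {f.logical_id!r}: length {len(nt)} not a multiple of 3; "
                    "trailing bases ignored")
            aa = str(Seq(nt[:len(nt) - len(nt) % 3]).translate(table=_BACTERIAL_TABLE))
            aa = aa.rstrip("*")
        if "*" in aa:
            warnings.warn(f"CDS {f.logical_id!r}: internal stop in translation; excluded")
            continue
        if not aa:
            continue
        out.append((f.logical_id, aa.replace("U", "X").replace("B", "X")
                    .replace("Z", "X").replace("J", "X")))
    return ProteinSet(genome.genome_id, out)


# ---------------------------------------------------------------------------
# masking


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mask_intervals(replicon: Replicon, intervals) -> Replicon:
    """Replace the given [start, end) positions by N; length unchanged."""
    n = len(replicon)
    for s, e in intervals:
        if not (0 <= s <= e <= n):
            raise GenomeValidationError(
                f"mask interval [{s},{e}) out of bounds for {replicon.id!r} (len {n})")
    seq = list(replicon.sequence)
    for s, e in merge_intervals(intervals):
        seq[s:e] = "N" * (e - s)
    return replace(replicon, sequence="".join(seq))


def mask_rrna(genome: GenomeRecord, extra_intervals: dict | None = None) -> GenomeRecord:
    """Mask annotated rRNA loci (plus optional per-replicon intervals).

    Returns a new record with masked replicon sequences and the masked
    intervals recorded in ``metadata['masked_intervals']``; recruitment
    requires this (or an explicit waiver) to avoid rRNA-driven biases.
    """
    per_rep: dict[str, list[tuple[int, int]]] = {r.id: [] for r in genome.replicons}
    for f in genome.features_of_type("rRNA"):
        per_rep[f.replicon_id].append((f.start, f.end))
    for rid, ivs in (extra_intervals or {}).items():
        per_rep.setdefault(rid, []).extend((int(s), int(e)) for s, e in ivs)
    masked = [mask_intervals(r, per_rep.get(r.id, [])) for r in genome.replicons]
    meta = dict(genome.metadata)
    meta["rrna_masked"] = True
    meta["masked_intervals"] = {rid: merge_intervals(ivs)
                                for rid, ivs in per_rep.items() if ivs}
    return GenomeRecord(genome.genome_id, masked, list(genome.features), meta)


# ---------------------------------------------------------------------------
# writing


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs as FASTA, 70 columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_genome_fasta(path, genome: GenomeRecord) -> None:
    write_fasta(path, [(r.id, r.sequence) for r in genome.replicons])


def write_proteins_fasta(path, proteins: ProteinSet) -> None:
    write_fasta(path, proteins.proteins)


def write_gff3(path, genome: GenomeRecord) -> None:
    """Emit features as GFF3 (internal 0-based half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.id} 1 {len(rep)}\n")
        for f in genome.features:
            attrs = [f"ID={f.feature_id}"]
            if f.logical_id != f.feature_id:
                attrs.append(f"logical_id={f.logical_id}")
            if f.product:
                attrs.append(f"product={f.product}")
            if f.partial:
                attrs.append("partial=true")
            fh.write("\t".join([
                f.replicon_id, "genostream", f.ftype,
                str(f.start + 1), str(f.end), ".", f.strand,
                "0" if f.ftype == "CDS" else ".", ";".join(attrs),
            ]) + "\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3 intervals (already 0-based half-open) per sequence id."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    return out
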