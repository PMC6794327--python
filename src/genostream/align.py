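"""Pairwise local alignment with BLAST-style statistics.

Smith-Waterman with affine gaps (Biopython's C aligner) plus
identity / similarity / coverage / bitscore / e-value computation.  This
is the computational substrate for orthology, paralogy, AAI and — via
the seeded nucleotide fast path in :mod:`genostream.identity` and
:mod:`genostream.recruit` — read recruitment.

E-values follow Karlin-Altschul: ``bitscore = (lambda*S - ln K)/ln 2``
and ``E = m*n*2**(-bitscore)`` with ``m`` the query length and ``n`` the
total subject search space.  The default constants are the standard
gapped values for BLOSUM62 (11/1) and for +2/-3 (5/2); thresholds, not
bit-for-bit BLAST parity, are the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

HIT_COLUMNS = ["qid", "sid", "pident", "psim", "alen", "qcov", "scov",
               "raw", "bitscore", "evalue", "self_hit"]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores, affine gap penalties and Karlin-Altschul constants.

    A gap of length g costs ``gap_open + g * gap_extend`` (BLAST's
    existence/extension convention).
    """

    kind: str  # 'protein' | 'nucleotide'
    matrix_name: str = "BLOSUM62"
    match: int = 2
    mismatch: int = -3
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self):
        if self.kind not in ("protein", "nucleotide"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(kind="protein")

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        # gapped +2/-3 with gap 5/2
        return cls(kind="nucleotide", gap_open=5.0, gap_extend=2.0,
                   karlin_lambda=0.625, karlin_k=0.41)

    @property
    def alphabet(self) -> str:
        return "ACDEFGHIKLMNPQRSTVWYBZXJUO*" if self.kind == "protein" else "ACGTN"

    def substitution_matrix(self):
        if self.kind == "protein":
            return substitution_matrices.load(self.matrix_name)
        return substitution_matrices.Array(
            alphabet="ACGTN", dims=2,
            data=[[self.match if (a == b and a != "N") else self.mismatch
                   for b in "ACGTN"] for a in "ACGTN"])

    def pair_score(self, a: str, b: str) -> float:
        m = self.substitution_matrix()
        return float(m[a, b])

    def make_aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.substitution_matrix()
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        if mode == "global":
            # cost-free terminal gaps: family members differ mostly at the ends
            try:
                al.end_insertion_score = 0.0
                al.end_deletion_score = 0.0
            except AttributeError:  # Biopython < 1.86 naming
                al.target_end_gap_score = 0.0
                al.query_end_gap_score = 0.0
        return al

    def bitscore(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw))

    def min_raw_for_evalue(self, max_evalue: float, m: int, n: int) -> float:
        """Smallest raw score whose e-value is <= max_evalue at search space m*n."""
        bits = math.log2(max(m, 1) * max(n, 1) / max_evalue)
        return (bits * math.log(2) + math.log(self.karlin_k)) / self.karlin_lambda


@dataclass
class AlignmentResult:
    """Statistics of one pairwise local alignment."""

    query_id: str
    subject_id: str
    aligned_length: int
    identity_percent: float
    similarity_percent: float
    coverage_query_percent: float
    coverage_subject_percent: float
    raw_score: float
    bitscore: float
    evalue: float
    query_start: int = 0
    subject_start: int = 0
    n_identities: int = field(default=0, repr=False)

    def passes(self, min_identity=None, min_coverage=None, max_evalue=None,
               min_length=None, min_similarity=None) -> bool:
        cov = min(self.coverage_query_percent, self.coverage_subject_percent)
        return not (
            (min_identity is not None and self.identity_percent < min_identity)
            or (min_similarity is not None and self.similarity_percent < min_similarity)
            or (min_coverage is not None and cov < min_coverage)
            or (max_evalue is not None and self.evalue > max_evalue)
            or (min_length is not None and self.aligned_length < min_length)
        )


def _check_alphabet(seq: str, scheme: ScoringScheme, label: str) -> None:
    bad = set(seq.upper()) - set(scheme.alphabet)
    if bad:
        raise ValueError(
            f"{label}: letters {sorted(bad)} not in the {scheme.kind} alphabet")


def align_local(query: str, subject: str, scheme: ScoringScheme | None = None, *,
                query_id: str = "query", subject_id: str = "subject",
                search_space: int | None = None) -> AlignmentResult | None:
    """Optimal Smith-Waterman alignment and its BLAST-style statistics.

    ``search_space`` is the total subject space n for the e-value (defaults
    to ``len(subject)``).  Returns None when the optimal local score is
    not positive (fully unrelated sequences under the scheme).
    """
    scheme = scheme or ScoringScheme.protein_default()
    if not query or not subject:
        raise ValueError("empty sequence")
    query, subject = query.upper(), subject.upper()
    _check_alphabet(query, scheme, query_id)
    _check_alphabet(subject, scheme, subject_id)
    aligner = scheme.make_aligner("local")
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    return _stats_from_alignment(aln, query, subject, scheme, query_id,
                                 subject_id, search_space)


def _stats_from_alignment(aln, query, subject, scheme, query_id, subject_id,
                          search_space) -> AlignmentResult:
    matrix = scheme.substitution_matrix()
    qs, ss = aln[0], aln[1]  # gapped aligned strings
    ncols = len(qs)
    ident = simil = 0
    for a, b in zip(qs, ss):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
            simil += 1
        elif matrix[a, b] > 0:
            simil += 1
    qblocks, sblocks = aln.aligned
    qspan = int(qblocks[-1][1] - qblocks[0][0])
    sspan = int(sblocks[-1][1] - sblocks[0][0])
    n = search_space if search_space is not None else len(subject)
    raw = float(aln.score)
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id, aligned_length=ncols,
        identity_percent=100.0 * ident / ncols,
        similarity_percent=100.0 * simil / ncols,
        coverage_query_percent=100.0 * qspan / len(query),
        coverage_subject_percent=100.0 * sspan / len(subject),
        raw_score=raw, bitscore=scheme.bitscore(raw),
        evalue=scheme.evalue(raw, len(query), n),
        query_start=int(qblocks[0][0]), subject_start=int(sblocks[0][0]),
        n_identities=ident,
    )


def search(queries, subjects, scheme: ScoringScheme | None = None, *,
           min_identity: float | None = None, min_coverage: float | None = None,
           min_similarity: float | None = None, max_evalue: float | None = None,
           min_length: int | None = None, include_self: bool = True,
           ) -> pd.DataFrame:
    """All-vs-all batch search returning a HitTable DataFrame.

    ``queries``/``subjects`` are iterables of (id, sequence) (a
    :class:`~genostream.io.ProteinSet` works directly).  The e-value search
    space n is the summed subject length.  A raw-score gate derived from
    ``max_evalue`` (default 10) skips the alignment-path computation for
    hopeless pairs; the gate uses the aligner's exact optimal score, so no
    passing hit is ever lost.
    """
    scheme = scheme or ScoringScheme.protein_default()
    qlist = list(queries)
    slist = list(subjects)
    if not qlist or not slist:
        raise ValueError("empty query or subject set")
    n_space = sum(len(s) for _, s in slist)
    aligner = scheme.make_aligner("local")
    gate_e = max_evalue if max_evalue is not None else 10.0
    rows = []
    for qid, qseq in qlist:
        gate = scheme.min_raw_for_evalue(gate_e, len(qseq), n_space)
        for sid, sseq in slist:
            if qid == sid and not include_self:
                continue
            score = aligner.score(qseq, sseq)
            if score <= 0 or score < gate:
                continue
            res = _stats_from_alignment(
                aligner.align(qseq, sseq)[0], qseq, sseq, scheme, qid, sid,
                n_space)
            if res.passes(min_identity=min_identity, min_coverage=min_coverage,
                          min_similarity=min_similarity, max_evalue=max_evalue,
                          min_length=min_length):
                rows.append((qid, sid, res.identity_percent,
                             res.similarity_percent, res.aligned_length,
                             res.coverage_query_percent,
                             res.coverage_subject_percent, res.raw_score,
                             res.bitscore, res.evalue, qid == sid))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hit_table(path, hits: pd.DataFrame) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
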