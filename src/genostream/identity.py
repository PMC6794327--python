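"""Average nucleotide identity (ANI) and average amino-acid identity (AAI).

ANI follows the fragment-based protocol: the query genome is cut into
consecutive 1,020-bp fragments, each fragment is aligned to the subject
genome, and fragments are retained when their identity is >= 30% over an
alignable region of >= 70% of the fragment; ANI is the mean identity of
retained fragments (symmetric mean of both directions reported).  AAI is
the mean identity over reciprocal best-hit protein pairs at >= 30%
identity and >= 70% coverage.  ~95% ANI/AAI delineates species; an AAI
band of 65-70% delineates genera.

Fragment placement uses exact k-mer seeding on both strands followed by
a windowed alignment (edlib), with per-column identity computed from the
extended CIGAR; fragments with no seed are treated as non-alignable.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from genostream.align import ScoringScheme, search
from genostream.io import GenomeRecord, ProteinSet

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani_percent: float | None
    n_fragments_used: int
    reciprocal: bool = True

    @property
    def defined(self) -> bool:
        return self.ani_percent is not None and self.n_fragments_used >= 1


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    aai_percent: float | None
    n_pairs: int

    @property
    def defined(self) -> bool:
        return self.aai_percent is not None and self.n_pairs >= 1


# ---------------------------------------------------------------------------
# k-mer seeded window alignment (shared with recruitment)


def kmer_index(sequences: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    """Exact k-mer -> [(sequence_id, position)] over all forward sequences."""
    idx: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in sequences.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            idx.setdefault(kmer, []).append((sid, i))
    return idx


def _candidate_windows(query: str, idx, k: int, step: int,
                       max_windows: int = 3) -> list[tuple[str, int]]:
    """Most-supported (sequence_id, diagonal) candidates for one query."""
    votes: dict[tuple[str, int], int] = {}
    for qpos in range(0, len(query) - k + 1, step):
        kmer = query[qpos:qpos + k]
        for sid, spos in idx.get(kmer, ()):
            d = spos - qpos
            key = (sid, d - d % 32)  # bucket nearby diagonals
            votes[key] = votes.get(key, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [key for key, _ in ranked[:max_windows]]


def cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(columns, matches, mismatches, gap_runs) from an extended CIGAR."""
    cols = matches = mism = runs = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            matches += n
        elif ch == "X":
            mism += n
        elif ch in "ID":
            runs += 1
    return cols, matches, mism, runs


def align_in_window(query: str, subjects: dict[str, str], idx, k: int, *,
                    step: int = 1, margin: int = 64,
                    max_windows: int = 3) -> dict | None:
    """Best seeded windowed alignment of ``query`` against indexed subjects.

    Tries both strands; returns the hit with the most matching columns:
    ``{sid, strand, columns, matches, mismatches, gap_runs, start, end}``
    or None when no strand has a seed.
    """
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        for sid, diag in _candidate_windows(q, idx, k, step, max_windows):
            seq = subjects[sid]
            lo = max(0, diag - margin)
            hi = min(len(seq), diag + len(q) + margin + 32)
            window = seq[lo:hi]
            if not window:
                continue
            res = edlib.align(q, window, mode="HW", task="path")
            if res["editDistance"] < 0 or not res.get("cigar"):
                continue
            cols, matches, mism, runs = cigar_stats(res["cigar"])
            if best is None or matches > best["matches"]:
                s, e = res["locations"][0]
                best = {"sid": sid, "strand": strand, "columns": cols,
                        "matches": matches, "mismatches": mism,
                        "gap_runs": runs, "start": lo + s, "end": lo + e + 1,
                        "cigar": res["cigar"]}
    return best


# ---------------------------------------------------------------------------
# ANI


def _fragments(genome: GenomeRecord, fragment_bp: int):
    for rep in genome.replicons:
        for i in range(0, len(rep) - fragment_bp + 1, fragment_bp):
            yield rep.sequence[i:i + fragment_bp]


def best_local_segment(cigar: str, *, match: float = 2.0, mismatch: float = -3.0,
                       gap: float = -4.0) -> tuple[int, int]:
    """(columns, matches) of the maximum-scoring run of alignment columns.

    The infix (glocal) alignment spans the whole query even for unrelated
    sequences; trimming to the best-scoring contiguous segment restores
    local-alignment semantics, so random matches collapse to short
    segments that fail the alignable-length rule.
    """
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    cols = np.empty(sum(n for _, n in ops), dtype=np.int8)
    at = 0
    for ch, n in ops:
        cols[at:at + n] = 0 if ch == "=" else (1 if ch == "X" else 2)
        at += n
    score = np.where(cols == 0, match, np.where(cols == 1, mismatch, gap))
    best = cur = 0.0
    best_span = (0, 0)
    start = 0
    for i, s in enumerate(score):
        cur += s
        if cur <= 0:
            cur = 0.0
            start = i + 1
        elif cur > best:
            best = cur
            best_span = (start, i + 1)
    lo, hi = best_span
    seg = cols[lo:hi]
    return int(hi - lo), int((seg == 0).sum())


def _ani_one_direction(a: GenomeRecord, b: GenomeRecord, fragment_bp: int,
                       min_identity: float, min_alignable: float,
                       k: int) -> tuple[float | None, int]:
    subjects = {r.id: r.sequence for r in b.replicons}
    idx = kmer_index(subjects, k)
    identities = []
    for frag in _fragments(a, fragment_bp):
        hit = align_in_window(frag, subjects, idx, k, step=16)
        if hit is None or hit["columns"] == 0:
            continue
        ncols, nmatch = best_local_segment(hit["cigar"])
        if ncols == 0:
            continue
        ident = 100.0 * nmatch / ncols
        if ident >= min_identity and ncols >= min_alignable / 100.0 * len(frag):
            identities.append(ident)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def compute_ani(a: GenomeRecord, b: GenomeRecord, *, fragment_bp: int = 1020,
                min_identity: float = 30.0, min_alignable: float = 70.0,
                k: int = 16) -> ANIResult:
    """Symmetric fragment-based ANI (mean of both directions)."""
    ab, n_ab = _ani_one_direction(a, b, fragment_bp, min_identity, min_alignable, k)
    ba, n_ba = _ani_one_direction(b, a, fragment_bp, min_identity, min_alignable, k)
    vals = [v for v in (ab, ba) if v is not None]
    if not vals:
        return ANIResult(a.genome_id, b.genome_id, None, 0)
    return ANIResult(a.genome_id, b.genome_id, float(np.mean(vals)),
                     n_ab + n_ba, reciprocal=(ab is not None and ba is not None))


# ---------------------------------------------------------------------------
# AAI


def compute_aai(a: ProteinSet, b: ProteinSet, *, min_identity: float = 30.0,
                min_coverage: float = 70.0,
                scheme: ScoringScheme | None = None) -> AAIResult:
    """AAI over reciprocal best-hit protein pairs at the retention cutoffs."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty proteome")
    scheme = scheme or ScoringScheme.protein_default()
    hits = search(a, b, scheme, min_identity=min_identity,
                  min_coverage=min_coverage)
    if hits.empty:
        return AAIResult(a.genome_id, b.genome_id, None, 0)
    best_ab = hits.loc[hits.groupby("qid")["bitscore"].idxmax()]
    best_ba = hits.loc[hits.groupby("sid")["bitscore"].idxmax()]
    rbh = set(zip(best_ab.qid, best_ab.sid)) & set(zip(best_ba.qid, best_ba.sid))
    if not rbh:
        return AAIResult(a.genome_id, b.genome_id, None, 0)
    keep = hits[[pair in rbh for pair in zip(hits.qid, hits.sid)]]
    keep = keep.loc[keep.groupby("qid")["bitscore"].idxmax()]
    return AAIResult(a.genome_id, b.genome_id,
                     float(keep.pident.mean()), len(keep))


# ---------------------------------------------------------------------------
# rank delineation


def classify_rank(aai: AAIResult, ani: ANIResult | None = None, *,
                  species_cut: float = 95.0, genus_cut_low: float = 65.0,
                  genus_cut_high: float = 70.0) -> str:
    """Taxonomic rank call from ANI/AAI.

    same_species when ANI >= 95 or AAI >= 95; different_genus below the
    hard 65% AAI cutoff; same_genus at or above the 70% figure-level
    cutoff; ambiguous in between.
    """
    if not aai.defined:
        raise ValueError("rank call requires a defined AAI")
    if (ani is not None and ani.defined and ani.ani_percent >= species_cut) \
            or aai.aai_percent >= species_cut:
        return "same_species"
    if aai.aai_percent < genus_cut_low:
        return "different_genus"
    if aai.aai_percent >= genus_cut_high:
        return "same_genus"
    return "ambiguous"
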