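"""Profile-based detection of methylotrophy modules.

Reference proteins for one-carbon metabolism are grouped into modules
(methanol oxidation, PQQ biosynthesis, H4MPT-linked formaldehyde
oxidation, RuMP cycle, ...).  Within each module the references are
greedily clustered at 90% identity / 90% coverage (longest-first,
coverage on the shorter sequence), each cluster is aligned by
center-star progressive alignment, and the alignment becomes a
position-specific log-odds profile with Henikoff position-based
sequence weights.  E-values come from a Gumbel fit to the scores of
composition-preserving shuffled decoys; a proteome hit at e <= 1e-3
marks the profile's module present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from genostream.align import ScoringScheme, align_local

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_AA_INDEX["X"] = 20  # scores 0 against every column

# Robinson-Robinson background amino-acid frequencies
BACKGROUND = dict(zip(
    AA_ORDER,
    [0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
     0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
     0.05841, 0.06441, 0.01330, 0.03216],
))


class CalibrationError(ValueError):
    """Profile used before (or without) decoy calibration."""


@dataclass
class ModuleDefinition:
    """One metabolic module and its reference proteins."""

    module_id: str
    label: str
    references: list[tuple[str, str]]  # (protein_id, sequence)

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError(f"module {self.module_id!r} has zero reference proteins")


@dataclass
class ProfileModel:
    """Calibrated position-specific scoring profile for one reference cluster."""

    profile_id: str
    module_id: str
    member_ids: list[str]
    scores: np.ndarray = field(repr=False)  # (n_columns, 21), bits
    gap_open: float = 4.0
    gap_extend: float = 0.5
    gumbel_loc: float | None = None
    gumbel_scale: float | None = None

    @property
    def calibrated(self) -> bool:
        return self.gumbel_loc is not None and self.gumbel_scale is not None

    def score_sequence(self, seq: str) -> float:
        return float(_pssm_local_score(self.scores, encode(seq),
                                       self.gap_open, self.gap_extend))

    def evalue(self, score: float, n_sequences: int) -> float:
        if not self.calibrated:
            raise CalibrationError(
                f"profile {self.profile_id!r} is not calibrated")
        return n_sequences * float(stats.gumbel_r.sf(
            score, loc=self.gumbel_loc, scale=self.gumbel_scale))


def encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in seq], dtype=np.int64)


@njit(cache=True)
def _pssm_local_score(scores, seq, gap_open, gap_extend):
    """Best local affine-gap alignment score of a sequence to a profile."""
    ncol = scores.shape[0]
    n = seq.shape[0]
    prev_m = np.zeros(ncol + 1)
    prev_x = np.full(ncol + 1, -1e30)
    best = 0.0
    for i in range(1, n + 1):
        cur_m = np.zeros(ncol + 1)
        cur_x = np.full(ncol + 1, -1e30)
        cur_m[0] = 0.0
        y = -1e30  # gap in sequence (skipping profile columns), row i
        for j in range(1, ncol + 1):
            diag = prev_m[j - 1]
            if prev_x[j - 1] > diag:
                diag = prev_x[j - 1]
            m = diag + scores[j - 1, seq[i - 1]]
            if m < 0.0:
                m = 0.0
            cur_m[j] = m
            x = prev_m[j] - gap_open - gap_extend
            xe = prev_x[j] - gap_extend
            if xe > x:
                x = xe
            cur_x[j] = x
            yo = cur_m[j - 1] - gap_open - gap_extend
            ye = y - gap_extend
            y = yo if yo > ye else ye
            if y > cur_m[j]:
                cur_m[j] = y
            if cur_m[j] > best:
                best = cur_m[j]
        prev_m = cur_m
        prev_x = cur_x
    return best


# ---------------------------------------------------------------------------
# clustering


def cluster_references(refs, *, identity: float = 90.0, coverage: float = 90.0,
                       scheme: ScoringScheme | None = None) -> list[list[tuple[str, str]]]:
    """Greedy longest-first clustering at identity over the shorter sequence.

    Each sequence joins the first cluster whose representative matches it
    at >= identity% over >= coverage% of the shorter sequence, else founds
    a new cluster.
    """
    scheme = scheme or ScoringScheme.protein_default()
    ordered = sorted(refs, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[list[tuple[str, str]]] = []
    for pid, seq in ordered:
        placed = False
        for cl in clusters:
            rep_id, rep_seq = cl[0]
            res = align_local(seq, rep_seq, scheme, query_id=pid,
                              subject_id=rep_id)
            if res is None:
                continue
            shorter = min(len(seq), len(rep_seq))
            ident_short = 100.0 * res.n_identities / shorter
            cov_short = max(res.coverage_query_percent,
                            res.coverage_subject_percent)
            if ident_short >= identity and cov_short >= coverage:
                cl.append((pid, seq))
                placed = True
                break
        if not placed:
            clusters.append([(pid, seq)])
    return clusters


# ---------------------------------------------------------------------------
# multiple alignment (center star) and profile construction


def _center_star_msa(members, scheme: ScoringScheme) -> list[str]:
    """Gapped member rows from center-star progressive alignment."""
    if len(members) == 1:
        return [members[0][1]]
    aligner = scheme.make_aligner("global")
    # center = member with the highest summed alignment score to the others
    sums = []
    for i, (_, si) in enumerate(members):
        tot = sum(aligner.score(si, sj) for j, (_, sj) in enumerate(members)
                  if i != j)
        sums.append(tot)
    ci = int(np.argmax(sums))
    center = members[ci][1]
    lc = len(center)
    inserts_per = []  # per member: chars inserted before each center pos
    aligned_per = []  # per member: char aligned to each center pos
    others = [m for i, m in enumerate(members) if i != ci]
    for _, mseq in others:
        aln = aligner.align(center, mseq)[0]
        cg, mg = aln[0], aln[1]
        ins = [[] for _ in range(lc + 1)]
        ali = ["-"] * lc
        cpos = 0
        for a, b in zip(cg, mg):
            if a == "-":
                ins[cpos].append(b)
            else:
                if b != "-":
                    ali[cpos] = b
                cpos += 1
        inserts_per.append(ins)
        aligned_per.append(ali)
    ins_max = [max((len(ins[i]) for ins in inserts_per), default=0)
               for i in range(lc + 1)]
    rows = []
    order = list(range(len(members)))
    for idx in order:
        out = []
        if idx == ci:
            for i in range(lc):
                out.append("-" * ins_max[i])
                out.append(center[i])
            out.append("-" * ins_max[lc])
        else:
            oi = idx if idx < ci else idx - 1
            ins, ali = inserts_per[oi], aligned_per[oi]
            for i in range(lc):
                chunk = "".join(ins[i])
                out.append(chunk + "-" * (ins_max[i] - len(chunk)))
                out.append(ali[i])
            chunk = "".join(ins[lc])
            out.append(chunk + "-" * (ins_max[lc] - len(chunk)))
        rows.append("".join(out))
    return rows


def _henikoff_weights(rows: list[str]) -> np.ndarray:
    nseq = len(rows)
    ncol = len(rows[0])
    w = np.zeros(nseq)
    for j in range(ncol):
        col = [r[j] for r in rows]
        present = [c for c in col if c != "-"]
        if not present:
            continue
        counts: dict[str, int] = {}
        for c in present:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c != "-":
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.full(nseq, 1.0 / nseq)
    return w / w.sum()


def build_profile(members, *, profile_id: str, module_id: str = "",
                  n_decoys: int = 500, seed: int = 0, pseudocount: float = 1.0,
                  gap_open: float = 4.0, gap_extend: float = 0.5,
                  scheme: ScoringScheme | None = None) -> ProfileModel:
    """Align cluster members, derive column log-odds, calibrate on decoys.

    ``n_decoys = 0`` skips calibration; scanning then refuses to produce
    e-values until the profile is calibrated.
    """
    if not members:
        raise ValueError("profile needs at least one member sequence")
    scheme = scheme or ScoringScheme.protein_default()
    rows = _center_star_msa(list(members), scheme)
    weights = _henikoff_weights(rows)
    bg = np.array([BACKGROUND[a] for a in AA_ORDER])
    ncol = len(rows[0])
    cols = []
    import warnings as _warnings
    for j in range(ncol):
        counts = np.zeros(20)
        total = 0.0
        for i, r in enumerate(rows):
            c = r[j]
            if c == "-" or c == "X":
                continue
            counts[_AA_INDEX[c]] += weights[i]
            total += weights[i]
        if total == 0.0:
            _warnings.warn(f"profile {profile_id!r}: all-gap column {j} dropped")
            continue
        freq = (counts + pseudocount * bg) / (total + pseudocount)
        cols.append(np.log2(freq / bg))
    scores = np.zeros((len(cols), 21))
    scores[:, :20] = np.array(cols)
    model = ProfileModel(profile_id=profile_id, module_id=module_id,
                         member_ids=[m[0] for m in members], scores=scores,
                         gap_open=gap_open, gap_extend=gap_extend)
    if n_decoys > 0:
        calibrate(model, [m[1] for m in members], n_decoys=n_decoys, seed=seed)
    return model


def calibrate(model: ProfileModel, member_seqs, *, n_decoys: int = 500,
              seed: int = 0) -> ProfileModel:
    """Fit the Gumbel null from shuffled (composition-preserving) decoys."""
    if n_decoys <= 0:
        raise ValueError("calibration requires at least one decoy")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    seqs = list(member_seqs)
    for d in range(n_decoys):
        src = seqs[d % len(seqs)]
        decoy = "".join(rng.permutation(list(src)))
        scores[d] = model.score_sequence(decoy)
    loc, scale = stats.gumbel_r.fit(scores)
    model.gumbel_loc = float(loc)
    model.gumbel_scale = float(max(scale, 1e-6))
    return model


# ---------------------------------------------------------------------------
# scanning and the module matrix


def build_module_profiles(modules: list[ModuleDefinition], *,
                          identity: float = 90.0, coverage: float = 90.0,
                          n_decoys: int = 500, seed: int = 0,
                          scheme: ScoringScheme | None = None) -> list[ProfileModel]:
    """Cluster each module's references and build one profile per cluster."""
    out = []
    for mod in modules:
        clusters = cluster_references(mod.references, identity=identity,
                                      coverage=coverage, scheme=scheme)
        for k, cl in enumerate(clusters):
            out.append(build_profile(
                cl, profile_id=f"{mod.module_id}_c{k:02d}",
                module_id=mod.module_id, n_decoys=n_decoys,
                seed=seed + k, scheme=scheme))
    return out


def scan(proteome, profiles: list[ProfileModel],
         *, max_evalue: float = 1e-3) -> pd.DataFrame:
    """Best profile-vs-protein scores with calibrated e-values.

    The e-value multiplies the Gumbel tail probability by the number of
    sequences scanned.  Rows are hits at e <= max_evalue.
    """
    plist = list(proteome)
    n = len(plist)
    rows = []
    for model in profiles:
        if not model.calibrated:
            raise CalibrationError(
                f"profile {model.profile_id!r} is not calibrated")
        for pid, seq in plist:
            s = model.score_sequence(seq)
            e = model.evalue(s, n)
            if e <= max_evalue:
                rows.append((model.profile_id, model.module_id, pid, s, e))
    return pd.DataFrame(rows, columns=["profile_id", "module_id", "protein_id",
                                       "score", "evalue"])


def module_matrix(hits_by_genome: dict[str, pd.DataFrame],
                  modules: list[ModuleDefinition], profiles: list[ProfileModel],
                  *, min_profiles_hit: int = 1) -> pd.DataFrame:
    """Genomes x modules presence/absence from per-genome scan hits."""
    module_ids = [m.module_id for m in modules]
    profiles_per_module: dict[str, int] = {}
    for p in profiles:
        profiles_per_module[p.module_id] = profiles_per_module.get(p.module_id, 0) + 1
    for mid in module_ids:
        if profiles_per_module.get(mid, 0) == 0:
            raise ValueError(f"module {mid!r} has zero profiles")
    mat = pd.DataFrame(0, index=sorted(hits_by_genome), columns=module_ids,
                       dtype=int)
    for gid, hits in hits_by_genome.items():
        if hits.empty:
            continue
        n_hit = hits.groupby("module_id")["profile_id"].nunique()
        for mid, k in n_hit.items():
            if k >= min_profiles_hit:
                mat.loc[gid, mid] = 1
    return mat


# ---------------------------------------------------------------------------
# module definition I/O


def load_module_definitions(table_path, fasta_path) -> list[ModuleDefinition]:
    """Module TSV (module_id, label, protein_id) + reference protein FASTA."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path),
                                                                "fasta")}
    df = pd.read_csv(table_path, sep="\t")
    out = []
    for (mid, label), grp in df.groupby(["module_id", "label"], sort=True):
        refs = []
        for pid in grp.protein_id:
            if pid not in seqs:
                raise ValueError(f"module {mid!r}: protein {pid!r} missing "
                                 "from the reference FASTA")
            refs.append((pid, seqs[pid]))
        out.append(ModuleDefinition(mid, label, refs))
    return out
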