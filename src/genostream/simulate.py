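"""Synthetic annotated genomes, diverged genome sets and metagenomes.

Every generator is a pure function of (spec, seed) and returns a truth
record holding the realised value of every quantity the analysis
modules later estimate, so recovery can be asserted without downloads.

Codon choice reconciles the genomic GC target with the amino-acid usage
bias by an exponential tilt on synonymous codons: codon weights within
each synonymous family are proportional to ``exp(t * gc(codon))`` with a
single temperature ``t`` solved so that the expected coding GC equals
the target; intergenic spacers are drawn at the same GC.  Infeasible
combinations (an amino-acid bias whose codons cannot reach the GC
target) raise :class:`FeasibilityError` instead of silently missing.

Gene overlaps are planted as the 1-bp stop/start sharing motif between
co-oriented minus-strand neighbours, which keeps every CDS translation
and terminal stop codon exactly consistent with the genome sequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq

from Bio.Data import CodonTable

from genostream.identity import revcomp
from genostream.io import Feature, GenomeRecord, ProteinSet, Replicon
from genostream.profiles import AA_ORDER, BACKGROUND


class FeasibilityError(ValueError):
    """The requested spec cannot be realised (with an explanation)."""


_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in CODONS_BY_AA:
    CODONS_BY_AA[aa].sort()
STOPS = ("TAA", "TAG", "TGA")
_STOP_GC = np.array([0.0, 1.0, 1.0])


def _default_aa_freqs() -> np.ndarray:
    return np.array([BACKGROUND[a] for a in AA_ORDER])


# ---------------------------------------------------------------------------
# GC / codon machinery


def _codon_gc_tables():
    max_c = max(len(v) for v in CODONS_BY_AA.values())
    gc = np.zeros((20, max_c))
    ncod = np.zeros(20, dtype=int)
    codons = np.empty((20, max_c), dtype="<U3")
    for i, aa in enumerate(AA_ORDER):
        cods = CODONS_BY_AA[aa]
        ncod[i] = len(cods)
        for j, c in enumerate(cods):
            gc[i, j] = c.count("G") + c.count("C")
            codons[i, j] = c
    return gc, ncod, codons


_GC_TAB, _NCOD, _CODON_TAB = _codon_gc_tables()


def _codon_weights(t: float) -> np.ndarray:
    w = np.zeros_like(_GC_TAB)
    for i in range(20):
        n = _NCOD[i]
        raw = np.exp(t * _GC_TAB[i, :n])
        w[i, :n] = raw / raw.sum()
    return w


def _expected_codon_gc(t: float, p_aa: np.ndarray) -> float:
    w = _codon_weights(t)
    per_aa = (w * _GC_TAB).sum(axis=1)
    return float((p_aa * per_aa).sum())


def solve_codon_temperature(p_aa: np.ndarray, gc_target: float,
                            stop_bias: np.ndarray,
                            mean_interior_codons: float) -> float:
    """Tilt t such that expected coding GC (incl. start/stop) hits the target."""
    gc_stop = float((stop_bias * _STOP_GC).sum())
    L = mean_interior_codons

    def f(t):
        return (1.0 + gc_stop + L * _expected_codon_gc(t, p_aa)) / (3.0 * (L + 2.0)) \
            - gc_target

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        lo_gc = f(lo) + gc_target
        hi_gc = f(hi) + gc_target
        raise FeasibilityError(
            f"GC target {gc_target:.3f} unreachable with this amino-acid bias: "
            f"achievable coding GC range is [{lo_gc:.3f}, {hi_gc:.3f}]")
    return float(brentq(f, lo, hi, xtol=1e-10))


def _sample_codons(aa_idx: np.ndarray, cumw: np.ndarray,
                   rng: np.random.Generator) -> str:
    rows = cumw[aa_idx]
    u = rng.random(len(aa_idx))
    pick = (u[:, None] > rows).sum(axis=1)
    return "".join(_CODON_TAB[aa_idx, pick])


# ---------------------------------------------------------------------------
# specs and truth


@dataclass
class GenomeSpec:
    """Statistical description of one synthetic annotated genome.

    Defaults emulate a genome-streamlined pelagic methylotroph: 1.3 Mbp,
    36% GC, ~850 bp genes, ~60 bp spacers, strong TAA stop bias.
    """

    genome_id: str = "synth"
    size_bp: int = 1_300_000
    gc: float = 0.36
    cds_len_log_mu: float = 6.75   # ln bp; exp(mu) ~ 850 bp
    cds_len_log_sigma: float = 0.35
    igs_mean: float = 60.0
    overlap_rate: float = 0.05
    n_paralog_families: int = 0
    paralog_family_size: int = 2
    paralog_identity: float = 1.0  # pairwise within-family protein identity
    stop_bias: tuple = (0.8, 0.1, 0.1)  # TAA, TAG, TGA
    aa_freqs: dict | None = None
    n_histidine_kinases: int = 0
    n_sigma_factors: int = 0
    n_rrna: int = 0
    rrna_len: int = 1200
    circular: bool = True
    seed: int = 0

    def validate(self) -> None:
        sb = np.asarray(self.stop_bias, dtype=float)
        if sb.shape != (3,) or abs(sb.sum() - 1.0) > 1e-9 or (sb < 0).any():
            raise FeasibilityError("stop_bias must be 3 non-negative values summing to 1")
        if not 0.0 < self.gc < 1.0:
            raise FeasibilityError("gc must be in (0,1)")
        if not 0.0 <= self.overlap_rate <= 0.5:
            raise FeasibilityError("overlap_rate must be in [0, 0.5]")
        p = self.aa_freq_vector()
        if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
            raise FeasibilityError("aa_freqs must be non-negative and sum to 1")
        mean_gene = np.exp(self.cds_len_log_mu + self.cds_len_log_sigma ** 2 / 2)
        n_special = (self.n_paralog_families * self.paralog_family_size
                     + self.n_histidine_kinases + self.n_sigma_factors)
        need = n_special * (mean_gene + self.igs_mean) \
            + self.n_rrna * (self.rrna_len + self.igs_mean)
        if need > 0.9 * self.size_bp:
            raise FeasibilityError(
                f"size {self.size_bp} bp too small for the requested "
                f"{n_special} planted CDS and {self.n_rrna} rRNA features")

    def aa_freq_vector(self) -> np.ndarray:
        if self.aa_freqs is None:
            p = _default_aa_freqs()
        else:
            p = np.array([self.aa_freqs.get(a, 0.0) for a in AA_ORDER], dtype=float)
        return p / p.sum()


def write_truth(path, truth: dict) -> None:
    def cast(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=cast)


# ---------------------------------------------------------------------------
# protein-level helpers


def _pairwise_rate_for_identity(identity: float, p_aa: np.ndarray) -> float:
    """Per-member mutation rate giving the target pairwise identity.

    Replacements always change the residue, so two members mutated
    independently from one ancestor match when both are kept
    (``(1-r)^2``) or both mutated to the same new residue (collision
    probability c); solve ``(1-r)^2 + r^2 c = identity`` for r.
    """
    if identity >= 1.0:
        return 0.0
    # collision probability of two independent non-silent replacements
    c = float(sum(p_aa[a] * ((np.delete(p_aa, a) / (1.0 - p_aa[a])) ** 2).sum()
                  for a in range(20)))
    if identity <= c:
        raise FeasibilityError(
            f"pairwise identity target {identity} at or below the random "
            f"baseline {c:.3f}")

    def f(r):
        return (1 - r) ** 2 + r * r * c - identity

    return float(brentq(f, 0.0, 0.9999))


def _mutate_protein(seq: str, rate: float, p_aa: np.ndarray,
                    rng: np.random.Generator) -> str:
    """Mutate each residue w.p. ``rate`` to a *different* residue (bg-weighted)."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        a = _AAIDX.get(chars[i])
        if a is None:
            continue
        p = p_aa.copy()
        p[a] = 0.0
        chars[i] = AA_ORDER[rng.choice(20, p=p / p.sum())]
    return "".join(chars)


_AAIDX = {a: i for i, a in enumerate(AA_ORDER)}


def _random_protein(length: int, p_aa: np.ndarray,
                    rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=p_aa)
    return "".join(AA_ORDER[i] for i in idx)


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(spec: GenomeSpec):
    """Realise a spec: (GenomeRecord, ProteinSet, truth dict)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_aa = spec.aa_freq_vector()
    stop_bias = np.asarray(spec.stop_bias, dtype=float)
    mean_interior = np.exp(spec.cds_len_log_mu + spec.cds_len_log_sigma ** 2 / 2) / 3 - 2
    t = solve_codon_temperature(p_aa, spec.gc, stop_bias, mean_interior)
    w = _codon_weights(t)
    cumw = np.cumsum(w, axis=1)

    # planted proteins: paralog families first, then annotation classes
    planted: list[tuple[str, str]] = []  # (product label, protein or "")
    paralog_truth: dict[str, list[int]] = {}
    slot = 0
    r_mut = _pairwise_rate_for_identity(spec.paralog_identity, p_aa)
    for fam in range(spec.n_paralog_families):
        alen = max(30, int(round(np.exp(rng.normal(
            spec.cds_len_log_mu, spec.cds_len_log_sigma)) / 3)) - 2)
        ancestor = _random_protein(alen, p_aa, rng)
        paralog_truth[f"fam{fam:03d}"] = []
        for _ in range(spec.paralog_family_size):
            planted.append(("duplicated family protein",
                            _mutate_protein(ancestor, r_mut, p_aa, rng)))
            paralog_truth[f"fam{fam:03d}"].append(slot)
            slot += 1
    planted += [("sensor histidine kinase", "")] * spec.n_histidine_kinases
    planted += [("RNA polymerase sigma factor", "")] * spec.n_sigma_factors
    order = rng.permutation(len(planted)) if planted else []
    planted_queue = [planted[i] for i in order]
    slot_of_planted = {int(oi): k for k, oi in enumerate(order)}
    paralog_truth = {
        fam: sorted(slot_of_planted[s] for s in slots)
        for fam, slots in paralog_truth.items()
    }

    def igs_seq(n):
        if n == 0:
            return ""
        probs = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
        idx = rng.choice(4, size=n, p=probs)
        return "".join("ACGT"[i] for i in idx)

    parts: list[str] = []
    features: list[Feature] = []
    proteins: list[tuple[str, str]] = []
    pos = 0
    gene_i = 0
    rrna_left = spec.n_rrna
    stop_counts = {s: 0 for s in STOPS}
    overlap_pairs: list[tuple[str, str]] = []
    prev_cds: Feature | None = None
    reserve = 3 * (mean_interior + 2) + spec.igs_mean + 10

    while True:
        igs = int(rng.geometric(1.0 / spec.igs_mean))
        if rrna_left > 0:
            glen = spec.rrna_len
        else:
            aa_len = max(30, int(round(np.exp(rng.normal(
                spec.cds_len_log_mu, spec.cds_len_log_sigma)) / 3)) - 2)
            glen = 3 * (aa_len + 2)
        if pos + igs + glen + reserve > spec.size_bp:
            break
        # 1-bp overlap with the previous CDS instead of a spacer?
        overlap = (prev_cds is not None and rrna_left == 0
                   and prev_cds.strand == "-" and prev_cds.end == pos
                   and rng.random() < min(1.0, 2.0 * spec.overlap_rate))
        if not overlap:
            parts.append(igs_seq(igs))
            pos += igs
        if rrna_left > 0:
            seq = igs_seq(glen)
            fid = f"{spec.genome_id}_r{rrna_left:02d}"
            features.append(Feature(fid, spec.genome_id, pos, pos + glen,
                                    "+", "rRNA", product="16S ribosomal RNA"))
            parts.append(seq)
            pos += glen
            rrna_left -= 1
            prev_cds = None
            continue
        # CDS
        if planted_queue:
            product, aa = planted_queue.pop(0)
            if aa:
                aa_len = len(aa)
                glen = 3 * (aa_len + 2)
            else:
                aa = _random_protein(aa_len, p_aa, rng)
        else:
            product, aa = "hypothetical protein", _random_protein(aa_len, p_aa, rng)
        if overlap:
            stop_i = int(rng.choice(3, p=np.array([stop_bias[0], 0.0, stop_bias[2]])
                                    / (stop_bias[0] + stop_bias[2])))
            strand = "-"
        else:
            stop_i = int(rng.choice(3, p=stop_bias))
            strand = "+" if rng.random() < 0.5 else "-"
        stop = STOPS[stop_i]
        stop_counts[stop] += 1
        aa_idx = np.array([AA_ORDER.index(c) for c in aa])
        nt = "ATG" + _sample_codons(aa_idx, cumw, rng) + stop
        fid = f"{spec.genome_id}_{gene_i:05d}"
        if overlap:
            start = pos - 1
            parts.append(revcomp(nt)[1:])
            pos = start + len(nt)
            overlap_pairs.append((prev_cds.feature_id, fid))
        else:
            start = pos
            parts.append(revcomp(nt) if strand == "-" else nt)
            pos += len(nt)
        feat = Feature(fid, spec.genome_id, start, start + len(nt), strand,
                       "CDS", product=product)
        features.append(feat)
        proteins.append((fid, "M" + aa))
        prev_cds = feat
        gene_i += 1

    parts.append(igs_seq(spec.size_bp - pos))
    sequence = "".join(parts)
    genome = GenomeRecord(
        spec.genome_id,
        [Replicon(spec.genome_id, sequence, circular=spec.circular)],
        features,
        metadata={"synthetic": True, "seed": spec.seed},
    )
    cds_feats = [f for f in features if f.ftype == "CDS"]
    pid_of_slot = {k: f.feature_id for k, f in enumerate(cds_feats)}
    n_cds = len(cds_feats)
    overlapping = {p for pair in overlap_pairs for p in pair}
    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "codon_temperature": t,
        "n_cds": n_cds,
        "n_rrna": spec.n_rrna,
        "genome_size_bp": len(sequence),
        "gc_target_percent": 100.0 * spec.gc,
        "mean_cds_bp": float(np.mean([f.length for f in cds_feats])),
        "stop_counts": stop_counts,
        "overlap_pairs": overlap_pairs,
        "overlapping_cds_percent": 100.0 * len(overlapping) / n_cds if n_cds else 0.0,
        "paralog_families": {fam: [pid_of_slot[s] for s in slots]
                             for fam, slots in paralog_truth.items()},
        "n_paralog_proteins": sum(len(v) for v in paralog_truth.values()),
        "n_histidine_kinases": spec.n_histidine_kinases,
        "n_sigma_factors": spec.n_sigma_factors,
    }
    return genome, ProteinSet(spec.genome_id, proteins), truth


# ---------------------------------------------------------------------------
# divergence


def evolve_genome(genome: GenomeRecord, nt_divergence: float, *,
                  gene_loss_fraction: float = 0.0, gene_gain_count: int = 0,
                  seed: int = 0, genome_id: str | None = None):
    """Mutate, delete and gain genes: (GenomeRecord, truth dict).

    Substitutions are placed uniformly (selection-agnostic); lost CDS are
    removed with their intervals closed; gained genes are drawn fresh and
    inserted into intergenic positions.  CDS overlapping another feature
    are never chosen for loss, so survivors keep exact frames.
    """
    if not 0.0 <= nt_divergence <= 0.3:
        raise ValueError("nt_divergence must be within [0, 0.3]")
    rng = np.random.default_rng(seed)
    gid = genome_id or genome.genome_id + "_evolved"
    new_reps: list[Replicon] = []
    feats = [Feature(f.feature_id, f.replicon_id, f.start, f.end, f.strand,
                     f.ftype, f.product, None, f.partial, f.logical_id)
             for f in genome.features]
    n_subs = 0
    alternatives = {b: "ACGT".replace(b, "") for b in "ACGT"}

    # candidate losses: CDS not overlapping any other feature
    lost_ids: set[str] = set()
    if gene_loss_fraction > 0:
        per_rep: dict[str, list[Feature]] = {}
        for f in feats:
            per_rep.setdefault(f.replicon_id, []).append(f)
        candidates = []
        for fl in per_rep.values():
            fl.sort(key=lambda f: f.start)
            for i, f in enumerate(fl):
                if f.ftype != "CDS":
                    continue
                prev_olap = i > 0 and fl[i - 1].end > f.start
                next_olap = i + 1 < len(fl) and fl[i + 1].start < f.end
                if not prev_olap and not next_olap:
                    candidates.append(f.feature_id)
        n_lose = int(round(gene_loss_fraction * len(candidates)))
        lost_ids = set(rng.choice(candidates, size=n_lose, replace=False)) \
            if n_lose else set()

    for rep in genome.replicons:
        arr = np.frombuffer(rep.sequence.encode(), dtype="S1").copy()
        if nt_divergence > 0:
            hit = np.nonzero(rng.random(len(arr)) < nt_divergence)[0]
            for i in hit:
                b = arr[i].decode()
                if b == "N":
                    continue
                arr[i] = alternatives[b][rng.integers(3)].encode()
                n_subs += 1
        seq = arr.tobytes().decode()
        # close the intervals of lost genes
        dels = sorted((f.start, f.end) for f in feats
                      if f.replicon_id == rep.id and f.feature_id in lost_ids)
        if dels:
            pieces, prev = [], 0
            for s, e in dels:
                pieces.append(seq[prev:s])
                prev = e
            pieces.append(seq[prev:])
            seq = "".join(pieces)

            def shift(x, dels=dels):
                return x - sum(e - s for s, e in dels if e <= x)

            for f in feats:
                if f.replicon_id == rep.id and f.feature_id not in lost_ids:
                    f.start, f.end = shift(f.start), shift(f.end)
        new_reps.append(Replicon(rep.id, seq, circular=rep.circular))

    feats = [f for f in feats if f.feature_id not in lost_ids]

    gained_ids: list[str] = []
    if gene_gain_count > 0:
        p_aa = _default_aa_freqs()
        cumw = np.cumsum(_codon_weights(0.0), axis=1)
        for gi in range(gene_gain_count):
            rep = new_reps[int(rng.integers(len(new_reps)))]
            aa_len = int(rng.integers(120, 400))
            aa = _random_protein(aa_len, p_aa, rng)
            aa_idx = np.array([AA_ORDER.index(c) for c in aa])
            nt = "ATG" + _sample_codons(aa_idx, cumw, rng) + "TAA"
            occupied = sorted((f.start, f.end) for f in feats
                              if f.replicon_id == rep.id)
            for _ in range(200):
                at = int(rng.integers(len(rep)))
                if all(not (s < at < e) for s, e in occupied):
                    break
            else:
                continue
            seq = rep.sequence[:at] + nt + rep.sequence[at:]
            idx = new_reps.index(rep)
            new_reps[idx] = Replicon(rep.id, seq, circular=rep.circular)
            for f in feats:
                if f.replicon_id == rep.id and f.start >= at:
                    f.start += len(nt)
                    f.end += len(nt)
            fid = f"{gid}_gain{gi:03d}"
            feats.append(Feature(fid, rep.id, at, at + len(nt), "+", "CDS",
                                 product="hypothetical protein"))
            gained_ids.append(fid)

    evolved = GenomeRecord(gid, new_reps, feats,
                           metadata={**genome.metadata, "parent": genome.genome_id})
    truth = {
        "parent": genome.genome_id,
        "nt_divergence": nt_divergence,
        "n_substitutions": int(n_subs),
        "lost_genes": sorted(lost_ids),
        "gained_genes": gained_ids,
        "expected_ani_percent": 100.0 * (1.0 - nt_divergence),
    }
    return evolved, truth


def evolve_proteome(proteins: ProteinSet, divergence: float, *, seed: int = 0,
                    genome_id: str | None = None):
    """Independently mutate each protein at the given residue divergence."""
    rng = np.random.default_rng(seed)
    p_aa = _default_aa_freqs()
    out = [(pid, _mutate_protein(seq, divergence, p_aa, rng))
           for pid, seq in proteins]
    truth = {"parent": proteins.genome_id, "divergence": divergence,
             "expected_identity_percent": 100.0 * (1.0 - divergence)}
    return ProteinSet(genome_id or proteins.genome_id + "_evolved", out), truth


# ---------------------------------------------------------------------------
# metagenomes


def generate_metagenome(sources, n_reads: int, *, read_len: int = 100,
                        error_rate: float = 0.01, metagenome_id: str = "synthmg",
                        ecosystem: str = "other", seed: int = 0):
    """Sample reads from genomes at known abundances: (ReadSet, truth).

    ``sources`` is a list of (GenomeRecord, abundance); abundances must sum
    to <= 1, the remainder being random background sequence at 50% GC.
    """
    from genostream.recruit import ReadSet

    rng = np.random.default_rng(seed)
    abund = np.array([a for _, a in sources], dtype=float)
    if (abund < 0).any() or abund.sum() > 1.0 + 1e-9:
        raise ValueError("abundances must be non-negative and sum to <= 1")
    for g, _ in sources:
        if any(len(r) < read_len for r in g.replicons):
            raise ValueError(
                f"read_len {read_len} exceeds a replicon of {g.genome_id!r}")
    probs = np.append(abund, max(0.0, 1.0 - abund.sum()))
    which = rng.choice(len(probs), size=n_reads, p=probs / probs.sum())
    reads, origins = [], []
    for i, src in enumerate(which):
        rid = f"{metagenome_id}_{i:06d}"
        if src == len(sources):  # background
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=read_len))
            origins.append("background")
        else:
            g = sources[src][0]
            lens = np.array([len(r) for r in g.replicons], dtype=float)
            rep = g.replicons[int(rng.choice(len(lens), p=lens / lens.sum()))]
            at = int(rng.integers(0, len(rep) - read_len + 1))
            seq = rep.sequence[at:at + read_len]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            if error_rate > 0:
                chars = list(seq)
                for j in np.nonzero(rng.random(read_len) < error_rate)[0]:
                    if chars[j] != "N":
                        chars[j] = "ACGT".replace(chars[j], "")[rng.integers(3)]
                seq = "".join(chars)
            origins.append(g.genome_id)
        reads.append((rid, seq))
    counts: dict[str, int] = {}
    for o in origins:
        counts[o] = counts.get(o, 0) + 1
    truth = {
        "n_reads": n_reads, "read_len": read_len, "error_rate": error_rate,
        "abundances": {g.genome_id: float(a) for g, a in sources},
        "reads_per_source": counts,
        "read_origin": dict(zip((r for r, _ in reads), origins)),
    }
    return ReadSet(metagenome_id, reads, ecosystem), truth


# ---------------------------------------------------------------------------
# protein families and pangenomes


def generate_protein_family(length: int, n_members: int, divergence: float,
                            n_decoys: int, *, seed: int = 0,
                            family_id: str = "fam"):
    """Ancestor + mutated members + composition-preserving shuffled decoys."""
    if n_members < 1:
        raise ValueError("need at least one member")
    rng = np.random.default_rng(seed)
    p_aa = _default_aa_freqs()
    ancestor = _random_protein(length, p_aa, rng)
    members = [(f"{family_id}_m{i:02d}",
                _mutate_protein(ancestor, divergence, p_aa, rng))
               for i in range(n_members)]
    decoys = []
    for d in range(n_decoys):
        src = members[d % n_members][1]
        decoys.append((f"{family_id}_decoy{d:03d}",
                       "".join(rng.permutation(list(src)))))
    truth = {"ancestor": ancestor, "divergence": divergence,
             "member_ids": [m for m, _ in members], "n_decoys": n_decoys}
    return members, decoys, truth


def generate_pangenome(n_genomes: int = 4, n_core: int = 50,
                       n_accessory: int = 30, *, family_identity: float = 0.7,
                       n_multicopy_core: int = 0, protein_len: int = 120,
                       seed: int = 0):
    """Planted ortholog families across genomes: (proteomes, truth).

    Core families appear in every genome, accessory families in a random
    proper subset; members share the given pairwise identity.  The first
    ``n_multicopy_core`` core families carry a duplicated member in the
    first genome (for single-copy-core filtering tests).
    """
    rng = np.random.default_rng(seed)
    p_aa = _default_aa_freqs()
    r = _pairwise_rate_for_identity(family_identity, p_aa)
    genome_ids = [f"G{i:02d}" for i in range(n_genomes)]
    proteins: dict[str, list[tuple[str, str]]] = {g: [] for g in genome_ids}
    fam_truth: dict[str, dict] = {}
    for fi in range(n_core + n_accessory):
        fam = f"fam{fi:03d}"
        core = fi < n_core
        ancestor = _random_protein(protein_len, p_aa, rng)
        if core:
            members_in = list(range(n_genomes))
        else:
            k = int(rng.integers(1, n_genomes))
            members_in = sorted(rng.choice(n_genomes, size=k, replace=False))
        fam_truth[fam] = {"core": core, "genomes": [genome_ids[i] for i in members_in],
                          "members": []}
        for gi in members_in:
            pid = f"{genome_ids[gi]}_{fam}"
            proteins[genome_ids[gi]].append(
                (pid, _mutate_protein(ancestor, r, p_aa, rng)))
            fam_truth[fam]["members"].append((genome_ids[gi], pid))
        if core and fi < n_multicopy_core:
            pid = f"{genome_ids[0]}_{fam}_copy2"
            proteins[genome_ids[0]].append(
                (pid, _mutate_protein(ancestor, r, p_aa, rng)))
            fam_truth[fam]["members"].append((genome_ids[0], pid))
    proteomes = [ProteinSet(g, proteins[g]) for g in genome_ids]
    truth = {"n_core": n_core, "n_accessory": n_accessory,
             "pan_families": n_core + n_accessory,
             "family_identity": family_identity,
             "mutation_rate": r, "families": fam_truth}
    return proteomes, truth


# ---------------------------------------------------------------------------
# profile-level cohorts for the statistics layer

# field: (intercept, slope, noise sd); x is genome size in Mbp for the
# architecture block and GC% for the usage/composition block.
DEFAULT_GRADIENTS: dict[str, tuple[float, float, float]] = {
    "gc_percent": (30.0, 7.0, 1.0),
    "mean_igs_bp": (20.0, 35.0, 8.0),
    "coding_density_percent": (97.0, -2.5, 0.5),
    "mean_cds_bp": (850.0, 60.0, 25.0),
    "overlapping_cds_percent": (22.0, -4.0, 1.5),
    "n_paralogs": (-40.0, 90.0, 12.0),
    "n_histidine_kinases": (-8.0, 14.0, 3.0),
    "n_sigma_factors": (-4.0, 8.0, 1.5),
    "stop_taa_percent": (120.0, -1.4, 2.0),
    "stop_tag_percent": (-20.0, 0.9, 2.0),
    "lys_percent": (14.0, -0.16, 0.3),
    "arg_percent": (-1.0, 0.13, 0.3),
    "c_per_aa": (5.4, -0.012, 0.01),
    "n_per_aa": (1.20, 0.004, 0.003),
    "s_per_aa": (0.020, 0.0003, 0.0008),
}

_GC_DRIVEN = {"stop_taa_percent", "stop_tag_percent", "lys_percent",
              "arg_percent", "c_per_aa", "n_per_aa", "s_per_aa"}


def generate_profile_cohort(n: int = 50, *, seed: int = 0,
                            size_range_mbp: tuple = (1.2, 3.3),
                            gradients: dict | None = None):
    """Profile-level cohort with planted linear gradients: (profiles, truth).

    Architecture metrics respond linearly to genome size (Mbp), usage and
    composition metrics to the realised GC%; noise is Gaussian.  Passing a
    gradient of slope 0 makes that metric independent of its driver (used
    for null calibration).
    """
    rng = np.random.default_rng(seed)
    grads = dict(DEFAULT_GRADIENTS)
    grads.update(gradients or {})
    sizes = rng.uniform(*size_range_mbp, size=n)
    rows = []
    for i in range(n):
        size = sizes[i]
        row = {"genome_id": f"cohort{i:03d}",
               "genome_size_bp": int(size * 1e6)}
        b, m, sd = grads["gc_percent"]
        gc = b + m * size + rng.normal(0.0, sd)
        row["gc_percent"] = gc
        for name, (b, m, sd) in grads.items():
            if name == "gc_percent":
                continue
            x = gc if name in _GC_DRIVEN else size
            val = b + m * x + rng.normal(0.0, sd)
            if name.startswith("n_"):
                val = max(0.0, val)
            row[name] = val
        rows.append(row)
    truth = {"n": n, "gradients": {k: list(v) for k, v in grads.items()},
             "size_range_mbp": list(size_range_mbp)}
    return rows, truth
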