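"""Cross-genome protein families, core/pan-genome summaries and paralogs.

Orthologous families are connected components (single linkage) of the
graph whose edges are reciprocal best hits between genomes passing the
ortholog cutoffs (>=50% identity, >=50% coverage by default).  Paralogs
are proteins with at least one non-self within-genome hit at >=80%
coverage, >=70% similarity and >=50% identity.  Coverage is always the
minimum of query and subject coverage (conservative reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from genostream.align import ScoringScheme, search
from genostream.io import ProteinSet, write_fasta

log = logging.getLogger(__name__)

ORTHOLOG_CUTOFFS = {"min_identity": 50.0, "min_coverage": 50.0}
PARALOG_CUTOFFS = {"min_coverage": 80.0, "min_similarity": 70.0,
                   "min_identity": 50.0}


@dataclass
class OrthologFamilies:
    """Partition of all proteins into families.

    ``families`` maps family_id -> list of (genome_id, protein_id); ids are
    canonical (lexicographically smallest member), so family composition is
    independent of genome input order.
    """

    families: dict[str, list[tuple[str, str]]]
    genome_ids: list[str]

    def presence_matrix(self, counts: bool = False) -> pd.DataFrame:
        mat = pd.DataFrame(0, index=sorted(self.families),
                           columns=self.genome_ids, dtype=int)
        for fid, members in self.families.items():
            for gid, _ in members:
                mat.loc[fid, gid] += 1
        return mat if counts else (mat > 0).astype(int)

    def n_proteins(self) -> int:
        return sum(len(m) for m in self.families.values())

    def to_table(self) -> pd.DataFrame:
        rows = [(fid, gid, pid) for fid, members in sorted(self.families.items())
                for gid, pid in members]
        return pd.DataFrame(rows, columns=["family_id", "genome_id", "protein_id"])


@dataclass
class PangenomeSummary:
    n_genomes: int
    pan_families: int
    core_families: int
    core_fraction_percent: float
    accumulation_curve: list[float] = field(default_factory=list)


def _pairwise_reciprocal_hits(pa: ProteinSet, pb: ProteinSet, cutoffs,
                              scheme: ScoringScheme) -> set[tuple[str, str]]:
    """Passing hit pairs (protein_id_a, protein_id_b) between two genomes.

    The scoring scheme is symmetric and coverage is the min over the pair,
    so a hit passing a->b passes b->a as well: one search direction yields
    the reciprocal passing pairs.
    """
    hits = search(pa, pb, scheme, **cutoffs)
    if hits.empty:
        return set()
    return set(zip(hits.qid, hits.sid))


def build_families(proteomes: list[ProteinSet], *,
                   min_identity: float = 50.0, min_coverage: float = 50.0,
                   scheme: ScoringScheme | None = None) -> OrthologFamilies:
    """Single-linkage ortholog families over reciprocal passing best hits."""
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    for p in proteomes:
        if len(p) == 0:
            raise ValueError(f"proteome {p.genome_id!r} has zero proteins")
    scheme = scheme or ScoringScheme.protein_default()
    cutoffs = {"min_identity": min_identity, "min_coverage": min_coverage}
    order = sorted(range(len(proteomes)), key=lambda i: proteomes[i].genome_id)
    g = nx.Graph()
    for i in order:
        p = proteomes[i]
        for pid, _ in p:
            g.add_node((p.genome_id, pid))
    for ii, i in enumerate(order):
        for j in order[ii + 1:]:
            pa, pb = proteomes[i], proteomes[j]
            for a, b in _pairwise_reciprocal_hits(pa, pb, cutoffs, scheme):
                g.add_edge((pa.genome_id, a), (pb.genome_id, b))
    families: dict[str, list[tuple[str, str]]] = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        fid = "F__" + "__".join(members[0])
        families[fid] = members
    return OrthologFamilies(families, sorted(p.genome_id for p in proteomes))


def core_pan_summary(families: OrthologFamilies, *, n_permutations: int = 100,
                     seed: int = 0) -> PangenomeSummary:
    """Pan/core counts and a permutation-averaged accumulation curve."""
    presence = families.presence_matrix().to_numpy(dtype=bool)
    n_fam, n_gen = presence.shape
    if n_gen < 2:
        raise ValueError("summary needs families spanning >=2 genomes")
    core = int(presence.all(axis=1).sum())
    rng = np.random.default_rng(seed)
    curve = np.zeros(n_gen)
    for _ in range(n_permutations):
        order = rng.permutation(n_gen)
        seen = np.zeros(n_fam, dtype=bool)
        for k, gi in enumerate(order):
            seen |= presence[:, gi]
            curve[k] += seen.sum()
    curve /= n_permutations
    return PangenomeSummary(
        n_genomes=n_gen, pan_families=n_fam, core_families=core,
        core_fraction_percent=100.0 * core / n_fam,
        accumulation_curve=curve.tolist(),
    )


def find_paralogs(proteome: ProteinSet, *, min_coverage: float = 80.0,
                  min_similarity: float = 70.0, min_identity: float = 50.0,
                  scheme: ScoringScheme | None = None,
                  ) -> tuple[int, list[tuple[str, str]]]:
    """(paralog protein count, passing within-genome pairs).

    Self-hits are excluded by protein id, not sequence equality, so exact
    duplicate sequences still count as paralogs of each other.
    """
    if len(proteome) == 0:
        raise ValueError("empty proteome")
    scheme = scheme or ScoringScheme.protein_default()
    hits = search(proteome, proteome, scheme, min_identity=min_identity,
                  min_coverage=min_coverage, min_similarity=min_similarity,
                  include_self=False)
    if hits.empty:
        return 0, []
    pairs = sorted({tuple(sorted((q, s))) for q, s in zip(hits.qid, hits.sid)})
    involved = {p for pair in pairs for p in pair}
    return len(involved), pairs


def single_copy_core(families: OrthologFamilies) -> dict[str, list[tuple[str, str]]]:
    """Families with exactly one member in every genome."""
    counts = families.presence_matrix(counts=True)
    keep = counts.index[(counts == 1).all(axis=1)]
    if len(keep) == 0:
        log.warning("no single-copy core families found")
    return {fid: families.families[fid] for fid in keep}


def export_single_copy_core(families: OrthologFamilies,
                            proteomes: list[ProteinSet], outdir) -> list[str]:
    """Write one concatenation-ready FASTA per single-copy core family.

    Records within each file are ordered by genome id, so per-genome
    concatenation across files is consistent.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {p.genome_id: p.as_dict() for p in proteomes}
    written = []
    for k, (fid, members) in enumerate(sorted(single_copy_core(families).items())):
        path = outdir / f"core_{k:05d}.faa"
        write_fasta(path, [(gid, seqs[gid][pid])
                           for gid, pid in sorted(members)])
        written.append(str(path))
    return written
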