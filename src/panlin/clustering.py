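"""Greedy incremental protein clustering (CD-HIT semantics).

Records are sorted by length descending (ties broken by id) and each record
joins the first existing cluster whose representative it matches at
identity >= c (shorter-sequence denominator) and length ratio >= s
(len(short)/len(long)).  Otherwise it founds a new cluster with itself as
representative.  Member-to-representative comparison only; no transitive
closure.  The canonical sort makes the output deterministic regardless of
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .align_core import Scoring, align_global
from .sequence_io import SeqRecord


@dataclass(frozen=True)
class ClusterParams:
    c: float = 0.8   # identity threshold
    s: float = 0.9   # length-difference cutoff, len(short)/len(long)
    best: bool = False        # join best-identity cluster instead of first
    prefilter: bool = False   # k-mer prefilter (skip pairs sharing no word)
    word_size: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.c <= 1):
            raise ValueError(f"c must be in (0, 1], got {self.c}")
        if not (0 < self.s <= 1):
            raise ValueError(f"s must be in (0, 1], got {self.s}")


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)
    genomes_present: set[str] = field(default_factory=set)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    params: ClusterParams
    n_input: int
    genome_of: dict[str, str] = field(default_factory=dict)

    def membership(self) -> dict[str, int]:
        """Map record id -> cluster_id."""
        out: dict[str, int] = {}
        for cl in self.clusters:
            for m in cl.members:
                out[m] = cl.cluster_id
        return out

    def presence_sets(self, genome_ids: Sequence[str]) -> dict[str, set[int]]:
        """Map genome_id -> set of cluster ids present in that genome."""
        known = set(genome_ids)
        out: dict[str, set[int]] = {g: set() for g in genome_ids}
        for cl in self.clusters:
            for g in cl.genomes_present:
                if g not in known:
                    raise KeyError(f"unknown genome {g!r}")
                out[g].add(cl.cluster_id)
        return out


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(records: Iterable[SeqRecord],
                   params: ClusterParams | None = None,
                   scoring: Scoring | None = None) -> ClusterSet:
    """Cluster protein records greedily against cluster representatives."""
    params = params or ClusterParams()
    recs = list(records)
    if not recs:
        raise ValueError("greedy_cluster: empty input")
    for r in recs:
        if r.moltype != "aa":
            raise ValueError(f"greedy_cluster: record {r.id!r} is not protein")
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise ValueError("greedy_cluster: duplicate record ids")

    order = sorted(recs, key=lambda r: (-len(r.seq), r.id))
    clusters: list[Cluster] = []
    reps: list[SeqRecord] = []
    rep_kmers: list[set[str]] = []
    k = params.word_size

    for rec in order:
        chosen: int | None = None
        best_ident = -1.0
        rec_kmers = _kmers(rec.seq, k) if params.prefilter else None
        for ci, rep in enumerate(reps):
            # order guarantees len(rec) <= len(rep)
            if len(rec.seq) / len(rep.seq) < params.s:
                continue
            if rec_kmers is not None and rec_kmers.isdisjoint(rep_kmers[ci]):
                continue
            aln = align_global(rec, rep, scoring=scoring,
                               identity_policy="shorter")
            ident = aln.identity_pct / 100.0
            if ident >= params.c:
                if not params.best:
                    chosen = ci
                    break
                if ident > best_ident:
                    best_ident = ident
                    chosen = ci
        if chosen is None:
            clusters.append(Cluster(cluster_id=len(clusters),
                                    representative=rec.id,
                                    members=[rec.id],
                                    genomes_present={rec.genome_id}))
            reps.append(rec)
            if params.prefilter:
                rep_kmers.append(rec_kmers if rec_kmers is not None
                                 else _kmers(rec.seq, k))
        else:
            clusters[chosen].members.append(rec.id)
            clusters[chosen].genomes_present.add(rec.genome_id)

    return ClusterSet(clusters=clusters, params=params, n_input=len(recs),
                      genome_of={r.id: r.genome_id for r in recs})


def cluster_presence_matrix(cs: ClusterSet,
                            genome_ids: Sequence[str]) -> list[list[int]]:
    """Binary clusters x genomes presence matrix (row order = cluster_id)."""
    known = {g: j for j, g in enumerate(genome_ids)}
    mat = [[0] * len(genome_ids) for _ in cs.clusters]
    for i, cl in enumerate(cs.clusters):
        for g in cl.genomes_present:
            if g not in known:
                raise KeyError(f"unknown genome {g!r}")
            mat[i][known[g]] = 1
    return mat


def write_clstr(cs: ClusterSet, path: str | Path,
                lengths: dict[str, int] | None = None) -> None:
    """Write clusters in CD-HIT .clstr-compatible text."""
    with open(path, "w") as fh:
        for cl in cs.clusters:
            fh.write(f">Cluster {cl.cluster_id}\n")
            for i, m in enumerate(cl.members):
                ln = f"{lengths[m]}aa, " if lengths and m in lengths else ""
                mark = "*" if m == cl.representative else "at ..."
                fh.write(f"{i}\t{ln}>{m}... {mark}\n")


def write_cluster_tsv(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# cluster_id\trepresentative\tmember\tgenome\n")
        for cl in cs.clusters:
            for m in cl.members:
                fh.write(f"{cl.cluster_id}\t{cl.representative}\t{m}\t"
                         f"{cs.genome_of.get(m, '')}\n")
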