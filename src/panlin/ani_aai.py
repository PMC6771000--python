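"""Fragment-based average nucleotide identity (ANIb-style) and
reciprocal-best-hit average amino-acid identity (AAI).

ANIb chops the query genome into consecutive non-overlapping fragments
(default 1020 bp; a terminal fragment is kept if it is at least half the
fragment length), locates the best-matching subject region by exact k-mer
diagonal voting on both strands, and aligns the fragment to that region
with the exact local aligner.  A fragment contributes to the mean iff its
alignment covers >= 70% of the fragment at >= 30% identity (Goris/Richter
convention).  Seeding only selects the candidate window; identities come
from the optimal alignment.

AAI aligns every cross-proteome pair passing a cheap shared-word filter,
takes best hits in both directions from the same symmetric alignment
store (so aai(A,B) == aai(B,A) exactly), keeps reciprocal best hits that
satisfy evalue <= 1e-3, identity >= 30% and coverage >= 70% of the shorter
protein, and averages their identities.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align_core import Scoring, align_local
from .sequence_io import GenomeAssembly, SeqRecord

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ANIParams:
    fragment_len: int = 1020
    min_identity: float = 30.0   # percent, over alignment length
    min_coverage: float = 70.0   # percent of the fragment
    seed_k: int = 16
    window_pad: int = 150


@dataclass
class ANIResult:
    query_genome: str
    subject_genome: str
    ani_pct: float | None   # None when no fragment passed the gates
    n_fragments_total: int
    n_fragments_used: int
    aligned_fraction: float


@dataclass(frozen=True)
class AAIParams:
    evalue_max: float = 1e-3
    identity_min: float = 30.0       # percent, over alignment length
    min_shorter_cov: float = 70.0    # percent of the shorter protein
    prefilter_k: int = 4


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    aai_pct: float | None   # None when there are no RBH pairs
    n_rbh_pairs: int


def fragment_genome(asm: GenomeAssembly, fragment_len: int = 1020) -> list[SeqRecord]:
    """Chop replicons into consecutive windows; keep a terminal fragment
    iff it is >= fragment_len / 2."""
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    frags: list[SeqRecord] = []
    for rep in asm.replicons:
        n = len(rep.seq)
        start = 0
        while start < n:
            end = min(start + fragment_len, n)
            if end - start >= fragment_len or end - start >= fragment_len / 2:
                frags.append(SeqRecord(
                    id=f"{rep.id}|{start}-{end}", seq=rep.seq[start:end],
                    genome_id=asm.genome_id, moltype="nt"))
            start += fragment_len
    return frags


def _kmer_index(seq: str, k: int, max_hits: int = 64) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i:i + k]].append(i)
    return {w: ps for w, ps in idx.items() if len(ps) <= max_hits}


def _best_window(frag: str, index: dict[str, list[int]], k: int,
                 subj_len: int, pad: int) -> tuple[int, int, int] | None:
    """Diagonal-vote the fragment against the index; return the candidate
    (start, end, votes) window on the subject, or None if no seed hits."""
    votes: Counter[int] = Counter()
    for i in range(0, len(frag) - k + 1):
        for p in index.get(frag[i:i + k], ()):
            votes[p - i] += 1
    if not votes:
        return None
    diag, nv = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    start = max(0, diag - pad)
    end = min(subj_len, diag + len(frag) + pad)
    return start, end, nv


def anib(query: GenomeAssembly, subject: GenomeAssembly,
         params: ANIParams | None = None,
         scoring: Scoring | None = None) -> ANIResult:
    """One-way ANIb: mean identity of usable query fragments vs subject."""
    params = params or ANIParams()
    sc = scoring or Scoring.nucleotide()
    frags = fragment_genome(query, params.fragment_len)
    subj = "".join(rep.seq for rep in subject.replicons)
    index = _kmer_index(subj, params.seed_k)
    subj_rec_cache: dict[tuple[int, int], SeqRecord] = {}

    used = 0
    idents: list[float] = []
    aligned_bp = 0
    for frag in frags:
        best_aln = None
        for strand_seq in (frag.seq, revcomp(frag.seq)):
            win = _best_window(strand_seq, index, params.seed_k,
                               len(subj), params.window_pad)
            if win is None:
                continue
            start, end, _ = win
            key = (start, end)
            if key not in subj_rec_cache:
                subj_rec_cache[key] = SeqRecord(
                    id=f"w{start}", seq=subj[start:end],
                    genome_id=subject.genome_id, moltype="nt")
            q = SeqRecord(id=frag.id, seq=strand_seq,
                          genome_id=query.genome_id, moltype="nt")
            aln = align_local(q, subj_rec_cache[key], scoring=sc,
                              identity_policy="alignment")
            if best_aln is None or aln.score > best_aln.score:
                best_aln = aln
        if best_aln is None:
            continue
        cov = 100.0 * (best_aln.query_span[1] - best_aln.query_span[0]) / len(frag.seq)
        if best_aln.identity_pct >= params.min_identity and cov >= params.min_coverage:
            used += 1
            idents.append(best_aln.identity_pct)
            aligned_bp += best_aln.query_span[1] - best_aln.query_span[0]
    total_bp = sum(len(f.seq) for f in frags)
    return ANIResult(
        query_genome=query.genome_id, subject_genome=subject.genome_id,
        ani_pct=float(np.mean(idents)) if used else None,
        n_fragments_total=len(frags), n_fragments_used=used,
        aligned_fraction=aligned_bp / total_bp if total_bp else 0.0)


def anib_symmetric(a: GenomeAssembly, b: GenomeAssembly,
                   params: ANIParams | None = None) -> float | None:
    """Mean of the two one-way ANIb values (missing if either is missing)."""
    r1 = anib(a, b, params)
    r2 = anib(b, a, params)
    if r1.ani_pct is None or r2.ani_pct is None:
        return None
    return (r1.ani_pct + r2.ani_pct) / 2.0


def _shared_word(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return True  # too short to filter safely; align anyway
    words = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in words for i in range(len(b) - k + 1))


def aai(protA: Sequence[SeqRecord], protB: Sequence[SeqRecord],
        params: AAIParams | None = None,
        scoring: Scoring | None = None) -> AAIResult:
    """Reciprocal-best-hit AAI between two proteomes."""
    params = params or AAIParams()
    if not protA or not protB:
        raise ValueError("aai: both proteomes must be non-empty")
    genome_a = protA[0].genome_id
    genome_b = protB[0].genome_id
    db_size = sum(len(r.seq) for r in protB)

    # Alignments are computed on id-canonicalised pairs so results are
    # exactly symmetric under argument swap.
    hits: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for ra in protA:
        for rb in protB:
            if not _shared_word(ra.seq, rb.seq, params.prefilter_k):
                continue
            first, second = (ra, rb) if ra.id <= rb.id else (rb, ra)
            aln = align_local(first, second, scoring=scoring,
                              identity_policy="alignment", db_size=db_size)
            shorter = min(len(ra.seq), len(rb.seq))
            if len(first.seq) <= len(second.seq):
                span = aln.query_span[1] - aln.query_span[0]
            else:
                span = aln.subject_span[1] - aln.subject_span[0]
            cov = 100.0 * span / shorter if shorter else 0.0
            hits[(ra.id, rb.id)] = (aln.score, aln.identity_pct, cov, aln.evalue)

    def passes(v: tuple[float, float, float, float]) -> bool:
        _, ident, cov, ev = v
        return (ev <= params.evalue_max and ident >= params.identity_min
                and cov >= params.min_shorter_cov)

    def best_map(keys_by_query: dict[str, list[tuple[str, tuple]]]) -> dict[str, str]:
        out = {}
        for q, cands in keys_by_query.items():
            cands = [c for c in cands if passes(c[1])]
            if not cands:
                continue
            cands.sort(key=lambda c: (-c[1][0], c[0]))
            out[q] = cands[0][0]
        return out

    a_cands: dict[str, list] = defaultdict(list)
    b_cands: dict[str, list] = defaultdict(list)
    for (ia, ib), v in hits.items():
        a_cands[ia].append((ib, v))
        b_cands[ib].append((ia, v))
    best_a = best_map(a_cands)
    best_b = best_map(b_cands)

    rbh_idents = []
    for ia, ib in sorted(best_a.items()):
        if best_b.get(ib) == ia:
            rbh_idents.append(hits[(ia, ib)][1])
    n = len(rbh_idents)
    return AAIResult(genome_a=genome_a, genome_b=genome_b,
                     aai_pct=float(np.mean(rbh_idents)) if n else None,
                     n_rbh_pairs=n)
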