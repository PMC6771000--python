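"""Optimal pairwise alignment with identity and e-value metrics.

Global (end-to-end) and local alignments are computed exactly with an
affine-gap Gotoh algorithm; no heuristic seeding.  Two percent-identity
denominators are available:

* ``"shorter"`` — matches / length of the shorter sequence (CD-HIT
  convention; used for clustering and LinA typing),
* ``"alignment"`` — matches / alignment length (BLAST convention; used for
  local screening hits).

E-values use the Karlin–Altschul formula E = K * m * n * exp(-lambda * S)
with standard gapped BLOSUM62 constants (lambda = 0.267, K = 0.041).  This
is an approximation, adequate for thresholding at coarse cutoffs such as
1e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from . import _dp
from .sequence_io import SeqRecord

KA_LAMBDA = 0.267
KA_K = 0.041

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NT_ALPHABET = "ACGTN"

# Ambiguous residues that never count as a match, per molecule type.
_NON_MATCH = {"aa": {"X"}, "nt": {"N"}}


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix: np.ndarray
    alphabet: str
    gap_open: float
    gap_extend: float
    moltype: str

    @staticmethod
    @lru_cache(maxsize=None)
    def protein(name: str = "BLOSUM62", gap_open: float = 11.0,
                gap_extend: float = 1.0) -> "Scoring":
        mat = substitution_matrices.load(name)
        alpha = str(mat.alphabet)
        arr = np.asarray(mat, dtype=np.float64)
        return Scoring(matrix=arr, alphabet=alpha, gap_open=gap_open,
                       gap_extend=gap_extend, moltype="aa")

    @staticmethod
    @lru_cache(maxsize=None)
    def nucleotide(match: float = 2.0, mismatch: float = -3.0,
                   gap_open: float = 5.0, gap_extend: float = 2.0) -> "Scoring":
        k = len(NT_ALPHABET)
        arr = np.full((k, k), mismatch, dtype=np.float64)
        for i, c in enumerate(NT_ALPHABET):
            if c != "N":
                arr[i, i] = match
        return Scoring(matrix=arr, alphabet=NT_ALPHABET, gap_open=gap_open,
                       gap_extend=gap_extend, moltype="nt")

    @staticmethod
    def from_file(path: str | Path, gap_open: float = 11.0,
                  gap_extend: float = 1.0, moltype: str = "aa") -> "Scoring":
        """Load an NCBI-format substitution matrix file."""
        mat = substitution_matrices.read(str(path))
        return Scoring(matrix=np.asarray(mat, dtype=np.float64),
                       alphabet=str(mat.alphabet), gap_open=gap_open,
                       gap_extend=gap_extend, moltype=moltype)


def default_scoring(moltype: str) -> Scoring:
    return Scoring.protein() if moltype == "aa" else Scoring.nucleotide()


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    mode: str  # "global" | "local"
    matches: int
    aln_len: int
    identity_pct: float
    score: float
    query_cov: float
    subject_cov: float
    evalue: float | None = None
    aligned_query: str = ""
    aligned_subject: str = ""
    query_span: tuple[int, int] = (0, 0)  # 0-based half-open on the query
    subject_span: tuple[int, int] = (0, 0)


def percent_identity(matches: int, denominator_policy: str, *,
                     len_a: int | None = None, len_b: int | None = None,
                     aln_len: int | None = None) -> float:
    """Percent identity under an explicit denominator policy.

    ``"shorter"`` uses min(len_a, len_b); ``"alignment"`` uses aln_len.
    Rounding happens only at reporting time.
    """
    if denominator_policy == "shorter":
        if len_a is None or len_b is None:
            raise ValueError("shorter policy requires len_a and len_b")
        denom = min(len_a, len_b)
    elif denominator_policy == "alignment":
        if aln_len is None:
            raise ValueError("alignment policy requires aln_len")
        denom = aln_len
    else:
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    if denom <= 0:
        raise ValueError("zero denominator")
    if matches > denom:
        raise ValueError(f"matches ({matches}) exceed denominator ({denom})")
    return 100.0 * matches / denom


def karlin_altschul_evalue(score: float, query_len: int, db_size: int) -> float:
    return KA_K * query_len * db_size * math.exp(-KA_LAMBDA * score)


def _encode(seq: str, scoring: Scoring) -> np.ndarray:
    alpha = scoring.alphabet
    idx = {c: i for i, c in enumerate(alpha)}
    if scoring.moltype == "nt":
        fallback = idx["N"]
        idx.setdefault("U", idx["T"])
    else:
        fallback = idx.get("X", len(alpha) - 1)
    return np.array([idx.get(c, fallback) for c in seq], dtype=np.int64)


def _count_matches(aq: str, asub: str, moltype: str) -> tuple[int, int]:
    ambiguous = _NON_MATCH[moltype]
    matches = 0
    for x, y in zip(aq, asub):
        if x == y and x not in ambiguous and x != "-":
            matches += 1
    return matches, len(aq)


def _check_moltypes(a: SeqRecord, b: SeqRecord) -> str:
    if a.moltype != b.moltype:
        raise ValueError(
            f"mixed alphabets: {a.id!r} is {a.moltype}, {b.id!r} is {b.moltype}"
        )
    return a.moltype


def _traceback(a: str, b: str, i: int, j: int, state: int,
               pM, pX, pY, local: bool) -> tuple[str, str, int, int]:
    """Walk pointers back from (i, j, state); returns aligned strings and
    the 0-based start coordinates on each sequence."""
    qa: list[str] = []
    qb: list[str] = []
    while True:
        if not local and i == 0 and j == 0:
            break
        if state == 0:
            p = pM[i, j]
            qa.append(a[i - 1])
            qb.append(b[j - 1])
            i -= 1
            j -= 1
            if local and p == 3:
                break
            state = p
        elif state == 1:
            p = pX[i, j]
            qa.append(a[i - 1])
            qb.append("-")
            i -= 1
            state = p
        else:
            p = pY[i, j]
            qa.append("-")
            qb.append(b[j - 1])
            j -= 1
            state = p
    return "".join(reversed(qa)), "".join(reversed(qb)), i, j


def align_global(a: SeqRecord, b: SeqRecord, scoring: Scoring | None = None,
                 identity_policy: str = "shorter") -> AlignmentResult:
    """Optimal end-to-end alignment of two records."""
    moltype = _check_moltypes(a, b)
    sc = scoring or default_scoring(moltype)
    ai, bi = _encode(a.seq, sc), _encode(b.seq, sc)
    score, state, pM, pX, pY = _dp.gotoh_global(
        ai, bi, sc.matrix, float(sc.gap_open), float(sc.gap_extend))
    aq, asub, _, _ = _traceback(a.seq, b.seq, len(a.seq), len(b.seq), state,
                                pM, pX, pY, local=False)
    matches, aln_len = _count_matches(aq, asub, moltype)
    ident = percent_identity(matches, identity_policy,
                             len_a=len(a.seq), len_b=len(b.seq), aln_len=aln_len)
    return AlignmentResult(
        query_id=a.id, subject_id=b.id, mode="global", matches=matches,
        aln_len=aln_len, identity_pct=ident, score=float(score),
        query_cov=100.0, subject_cov=100.0,
        aligned_query=aq, aligned_subject=asub,
        query_span=(0, len(a.seq)), subject_span=(0, len(b.seq)))


def align_local(a: SeqRecord, b: SeqRecord, scoring: Scoring | None = None,
                identity_policy: str = "alignment",
                db_size: int | None = None) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment with an e-value estimate.

    ``db_size`` is the search-space size in residues (defaults to the
    subject length); it only affects the e-value.
    """
    moltype = _check_moltypes(a, b)
    sc = scoring or default_scoring(moltype)
    ai, bi = _encode(a.seq, sc), _encode(b.seq, sc)
    score, bi_, bj_, pM, pX, pY = _dp.gotoh_local(
        ai, bi, sc.matrix, float(sc.gap_open), float(sc.gap_extend))
    aq, asub, i0, j0 = _traceback(a.seq, b.seq, bi_, bj_, 0, pM, pX, pY,
                                  local=True)
    matches, aln_len = _count_matches(aq, asub, moltype)
    ident = percent_identity(matches, identity_policy,
                             len_a=len(a.seq), len_b=len(b.seq), aln_len=aln_len)
    n = db_size if db_size is not None else len(b.seq)
    ev = karlin_altschul_evalue(float(score), len(a.seq), n)
    return AlignmentResult(
        query_id=a.id, subject_id=b.id, mode="local", matches=matches,
        aln_len=aln_len, identity_pct=ident, score=float(score),
        query_cov=100.0 * (bi_ - i0) / len(a.seq),
        subject_cov=100.0 * (bj_ - j0) / len(b.seq),
        evalue=ev, aligned_query=aq, aligned_subject=asub,
        query_span=(i0, bi_), subject_span=(j0, bj_))
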