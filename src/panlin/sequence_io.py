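"""Sequence, genome and tree I/O plus basic genome statistics.

FASTA records are read with Biopython and validated against the expected
alphabet; Newick trees are parsed with DendroPy.  Coordinates in feature
tables are 1-based inclusive (GFF convention); all internal arithmetic is
0-based half-open, converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Residues accepted per alphabet.  IUPAC ambiguity codes are allowed; they
# simply never count as matches downstream.
NT_LETTERS = set("ACGTU" "RYSWKMBDHVN")
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY" "BJZXUO*")


@dataclass
class SeqRecord:
    """A single sequence with a stable id and genome membership."""

    id: str
    seq: str
    description: str = ""
    genome_id: str = ""
    moltype: str = "aa"  # "aa" or "nt"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r}: seq must be non-empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """An assembled genome: one or more nucleotide replicons."""

    genome_id: str
    replicons: list[SeqRecord]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError(f"GenomeAssembly {self.genome_id!r}: needs at least one replicon")
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"GenomeAssembly {self.genome_id!r}: duplicate replicon ids")

    @property
    def total_bp(self) -> int:
        return sum(len(r) for r in self.replicons)


@dataclass
class GenomeStats:
    total_bp: int
    gc_percent: float
    n_replicons: int
    replicon_lengths: list[int]
    coding_percent: float | None = None


def read_fasta(path: str | Path, alphabet: str = "aa", genome_id: str = "") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Parameters
    ----------
    path:
        FASTA file (folded or single-line).
    alphabet:
        ``"nt"`` or ``"aa"``; residues outside the alphabet (IUPAC ambiguity
        included) raise an error naming the offending position.
    genome_id:
        Genome membership stamped on every record.  Membership is always
        taken from the per-genome input file, never parsed from headers.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    letters = NT_LETTERS if alphabet == "nt" else AA_LETTERS
    records: list[SeqRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in letters:
                raise ValueError(
                    f"record {rec.id!r}: residue {ch!r} at position {pos} "
                    f"not in {alphabet} alphabet"
                )
        records.append(
            SeqRecord(id=rec.id, seq=seq, description=rec.description,
                      genome_id=genome_id, moltype=alphabet)
        )
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise ValueError(f"{path}: no records")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate id(s): {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def _gc_counts(seq: str) -> tuple[int, int]:
    """(gc, unambiguous) counts; ambiguity codes are excluded from both."""
    gc = sum(seq.count(c) for c in "GC")
    at = sum(seq.count(c) for c in "ATU")
    return gc, gc + at


def genome_stats(
    asm: GenomeAssembly,
    features: Sequence[tuple[str, int, int]] | None = None,
) -> GenomeStats:
    """Compute genome-level statistics.

    ``features`` is an optional iterable of ``(replicon_id, start, end)``
    intervals, 1-based inclusive, used for the coding fraction; overlapping
    intervals are counted once.
    """
    lengths = [len(r) for r in asm.replicons]
    total = sum(lengths)
    gc = unamb = 0
    for rep in asm.replicons:
        g, u = _gc_counts(rep.seq)
        gc += g
        unamb += u
    gc_percent = 100.0 * gc / unamb if unamb else 0.0

    coding: float | None = None
    if features is not None:
        rep_len = {r.id: len(r) for r in asm.replicons}
        by_rep: dict[str, list[tuple[int, int]]] = {}
        for rid, start, end in features:
            if rid not in rep_len:
                raise ValueError(f"feature interval on unknown replicon {rid!r}")
            if start < 1 or end > rep_len[rid] or start > end:
                raise ValueError(
                    f"feature interval out of bounds on {rid!r}: ({start}, {end})"
                )
            # 1-based inclusive -> 0-based half-open
            by_rep.setdefault(rid, []).append((start - 1, end))
        covered = 0
        for ivs in by_rep.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
            covered += cur_e - cur_s
        coding = 100.0 * covered / total
    return GenomeStats(
        total_bp=total,
        gc_percent=gc_percent,
        n_replicons=len(lengths),
        replicon_lengths=lengths,
        coding_percent=coding,
    )


def read_feature_table(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a TSV of (replicon_id, start, end, [strand, feature_id])."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


class PhyloTree:
    """A rooted or unrooted tree with branch lengths, keyed by leaf label."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
        if n_missing:
            logger.warning("newick tree: %d missing branch lengths set to 0", n_missing)
        self._pdm = tree.phylogenetic_distance_matrix()

    @property
    def newick_text(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    @property
    def leaves(self) -> set[str]:
        return {t.label for t in self._tree.taxon_namespace}

    def patristic_distance(self, a: str, b: str) -> float:
        ns = self._tree.taxon_namespace
        ta, tb = ns.get_taxon(a), ns.get_taxon(b)
        if ta is None or tb is None:
            missing = a if ta is None else b
            raise KeyError(f"leaf {missing!r} not in tree")
        return float(self._pdm.patristic_distance(ta, tb))

    def patristic_matrix(self, order: Sequence[str]) -> list[list[float]]:
        return [[0.0 if x == y else self.patristic_distance(x, y) for y in order]
                for x in order]


def read_newick(path_or_text: str | Path) -> PhyloTree:
    """Parse a Newick tree from a file path or a literal Newick string."""
    text: str
    p = Path(str(path_or_text))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_text)
        if not text.lstrip().startswith("("):
            raise FileNotFoundError(f"no such file: {path_or_text}")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree)


def nearest_patristic_distance(tree: PhyloTree, leaf: str) -> float:
    """Minimum patristic distance from *leaf* to any other leaf."""
    others = tree.leaves - {leaf}
    if leaf not in tree.leaves:
        raise KeyError(f"leaf {leaf!r} not in tree")
    if not others:
        raise ValueError("single-leaf tree: no relatives")
    return min(tree.patristic_distance(leaf, o) for o in others)
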