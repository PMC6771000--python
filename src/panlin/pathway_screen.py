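"""Homology screening against a labelled reference pathway database and
LinA dehydrochlorinase isoform typing.

Screen thresholds are applied strictly — a hit must have evalue < the
configured maximum and identity > the configured minimum; boundary values
are excluded.  Reference databases are plain FASTA with a ``route=`` token
in the header description.

LinA typing aligns the query globally to each reference variant (identity
on the shorter-sequence denominator), picks the best variant, and reads
diagnostic residues off the query at reference-frame positions projected
through the alignment: positions are 1-based on the 154-residue LinA
frame, so insertions in the query never shift them.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .align_core import Scoring, align_global, align_local
from .sequence_io import SeqRecord, read_fasta

LINA_POSITIONS = (20, 23, 25, 35, 73, 96, 129, 131)
CATALYTIC = {25: "D", 73: "H", 129: "R"}
MINUS_PREF = {20: "K", 96: "L", 131: "A"}


@dataclass
class ScreenHit:
    query_id: str
    genome_id: str
    ref_id: str
    route_label: str
    identity_pct: float
    query_cov: float
    evalue: float


@dataclass
class CopyNumberSummary:
    counts: dict[tuple[str, str], int]     # (genome, ref) -> distinct queries
    fraction_single: float
    fraction_double: float
    fraction_triple: float
    fraction_quad_plus: float


@dataclass
class LinAReport:
    query_id: str
    identities: dict[str, float]           # variant -> identity pct (unrounded)
    best_variant: str
    residues: dict[int, str] = field(default_factory=dict)
    catalytic_ok: bool = False
    enantiomer_call: str = "indeterminate"


def read_refdb(path: str | Path) -> list[tuple[SeqRecord, str]]:
    """Read a labelled reference FASTA; route taken from a ``route=`` token
    in the description (``unlabelled`` when absent)."""
    out = []
    for rec in read_fasta(path, alphabet="aa"):
        route = "unlabelled"
        for tok in rec.description.split():
            if tok.startswith("route="):
                route = tok[len("route="):]
        out.append((rec, route))
    return out


def load_toy_refdb() -> list[tuple[SeqRecord, str]]:
    """Small bundled reference database mimicking an aromatic-degradation
    route structure; for demos and smoke tests only."""
    with resources.as_file(resources.files("panlin") / "data" / "toy_refdb.faa") as p:
        return read_refdb(p)


def screen(proteome: Sequence[SeqRecord],
           refdb: Sequence[tuple[SeqRecord, str]],
           evalue_max: float = 1e-5, identity_min: float = 50.0,
           identity_policy: str = "alignment",
           scoring: Scoring | None = None) -> list[ScreenHit]:
    """Local-alignment screen of a proteome against the labelled refdb.

    Thresholds are strict: evalue < evalue_max AND identity > identity_min.
    """
    if not refdb:
        raise ValueError("screen: empty reference database")
    db_size = sum(len(r.seq) for r, _ in refdb)
    hits: list[ScreenHit] = []
    for q in proteome:
        for ref, route in refdb:
            aln = align_local(q, ref, scoring=scoring,
                              identity_policy=identity_policy,
                              db_size=db_size)
            if aln.evalue < evalue_max and aln.identity_pct > identity_min:
                hits.append(ScreenHit(
                    query_id=q.id, genome_id=q.genome_id, ref_id=ref.id,
                    route_label=route, identity_pct=aln.identity_pct,
                    query_cov=aln.query_cov, evalue=aln.evalue))
    hits.sort(key=lambda h: (h.genome_id, h.query_id, h.ref_id))
    return hits


def copy_number_summary(hits: Sequence[ScreenHit]) -> CopyNumberSummary:
    """Per-(genome, ref) distinct-query counts and global multiplicity
    fractions over (genome, ref) pairs with at least one hit."""
    queries: dict[tuple[str, str], set[str]] = defaultdict(set)
    for h in hits:
        queries[(h.genome_id, h.ref_id)].add(h.query_id)
    counts = {k: len(v) for k, v in queries.items()}
    dist = Counter(min(c, 4) for c in counts.values())
    total = sum(dist.values())
    frac = lambda n: dist.get(n, 0) / total if total else 0.0
    return CopyNumberSummary(
        counts=counts, fraction_single=frac(1), fraction_double=frac(2),
        fraction_triple=frac(3), fraction_quad_plus=frac(4))


def _project_residues(aln_query: str, aln_ref: str,
                      positions: Sequence[int]) -> dict[int, str]:
    """Query residues at 1-based reference positions, via alignment columns.
    Positions where the query has a gap are omitted."""
    wanted = set(positions)
    out: dict[int, str] = {}
    ref_pos = 0
    for qc, rc in zip(aln_query, aln_ref):
        if rc != "-":
            ref_pos += 1
            if ref_pos in wanted and qc != "-":
                out[ref_pos] = qc
    return out


def type_lina(query: SeqRecord, references: Mapping[str, SeqRecord],
              positions: Sequence[int] = LINA_POSITIONS,
              min_identity: float = 60.0,
              scoring: Scoring | None = None) -> LinAReport:
    """Type a LinA-like query against named reference variants."""
    if not references:
        raise ValueError("type_lina: no reference variants")
    identities: dict[str, float] = {}
    alns = {}
    for name in sorted(references):
        aln = align_global(query, references[name], scoring=scoring,
                           identity_policy="shorter")
        identities[name] = aln.identity_pct
        alns[name] = aln
    best = max(sorted(identities), key=lambda n: identities[n])
    if identities[best] < min_identity:
        return LinAReport(query_id=query.id, identities=identities,
                          best_variant="none")
    aln = alns[best]
    residues = _project_residues(aln.aligned_query, aln.aligned_subject,
                                 positions)
    catalytic_ok = all(residues.get(p) == r for p, r in CATALYTIC.items())
    if all(p in residues for p in MINUS_PREF):
        minus = all(residues[p] == r for p, r in MINUS_PREF.items())
        call = "minus_preferring" if minus else "plus_preferring"
    else:
        call = "indeterminate"
    return LinAReport(query_id=query.id, identities=identities,
                      best_variant=best, residues=residues,
                      catalytic_ok=catalytic_ok, enantiomer_call=call)


def write_hits_tsv(hits: Sequence[ScreenHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# genome\tquery\tref\troute\tidentity_pct\tevalue\tquery_cov\n")
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.query_id}\t{h.ref_id}\t{h.route_label}"
                     f"\t{h.identity_pct:.1f}\t{h.evalue:.3g}\t{h.query_cov:.1f}\n")


def write_lina_tsv(reports: Sequence[LinAReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# query\tbest_variant\tidentities\tresidues\tcatalytic_ok"
                 "\tenantiomer_call\n")
        for r in reports:
            idents = ",".join(f"{k}:{v:.1f}" for k, v in sorted(r.identities.items()))
            res = ",".join(f"{p}{a}" for p, a in sorted(r.residues.items()))
            fh.write(f"{r.query_id}\t{r.best_variant}\t{idents}\t{res}"
                     f"\t{r.catalytic_ok}\t{r.enantiomer_call}\n")


def format_lina_report(r: LinAReport) -> str:
    lines = [f"LinA typing for {r.query_id}",
             f"  best variant: {r.best_variant}"]
    for name, pct in sorted(r.identities.items(), key=lambda kv: -kv[1]):
        lines.append(f"  identity to {name}: {pct:.1f}%")
    if r.residues:
        res = ", ".join(f"{a}{p}" for p, a in sorted(r.residues.items()))
        lines.append(f"  residues: {res}")
    lines.append(f"  catalytic triad (D25/H73/R129) intact: "
                 f"{'yes' if r.catalytic_ok else 'no'}")
    lines.append(f"  enantiomer preference call: {r.enantiomer_call}")
    return "\n".join(lines)
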