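"""Ground-truth generators: pangenomes, genome pairs and variant sets.

Substitutions are uniform over alternative residues so expected identities
are analytically exact: per-site mutation at rate d gives expected identity
100 * (1 - d).  A count-exact mode substitutes at exactly the requested
positions for analytic fixtures.  All randomness flows through one
``numpy.random.default_rng(seed)``, so output is byte-identical under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import GenomeAssembly, SeqRecord, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

# Standard genetic code, codons grouped per amino acid.
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass(frozen=True)
class SyntheticPangenomeSpec:
    n_genomes: int = 5
    n_core: int = 50
    n_accessory: int = 20
    accessory_presence_p: float = 0.5
    n_unique_per_genome: int | Sequence[int] = 10
    within_family_divergence: float = 0.05
    protein_length_range: tuple[int, int] = (120, 300)
    gc_percent: float = 60.0
    seed: int = 0

    def unique_counts(self) -> list[int]:
        if isinstance(self.n_unique_per_genome, int):
            return [self.n_unique_per_genome] * self.n_genomes
        counts = list(self.n_unique_per_genome)
        if len(counts) != self.n_genomes:
            raise ValueError("n_unique_per_genome list length != n_genomes")
        return counts


@dataclass
class SyntheticTruth:
    gene_to_family: dict[str, str]
    family_class: dict[str, str]   # "core" | "accessory" | "unique:<genome>"
    expected_within_identity: float

    def class_counts(self) -> tuple[int, int, dict[str, int]]:
        core = sum(1 for c in self.family_class.values() if c == "core")
        acc = sum(1 for c in self.family_class.values() if c == "accessory")
        uniq: dict[str, int] = {}
        for c in self.family_class.values():
            if c.startswith("unique:"):
                g = c.split(":", 1)[1]
                uniq[g] = uniq.get(g, 0) + 1
        return core, acc, uniq


@dataclass
class SyntheticPangenome:
    spec: SyntheticPangenomeSpec
    proteomes: dict[str, list[SeqRecord]]
    assemblies: dict[str, GenomeAssembly]
    truth: SyntheticTruth
    newick: str

    def genome_ids(self) -> list[str]:
        return list(self.proteomes)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g, recs in self.proteomes.items():
            write_fasta(recs, outdir / f"{g}.faa")
        for g, asm in self.assemblies.items():
            write_fasta(asm.replicons, outdir / f"{g}.fna")
        (outdir / "tree.nwk").write_text(self.newick + "\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("# gene_id\tfamily_id\tclass\n")
            for gene, fam in sorted(self.truth.gene_to_family.items()):
                fh.write(f"{gene}\t{fam}\t{self.truth.family_class[fam]}\n")


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_sequence(rec: SeqRecord, d: float, seed: int | np.random.Generator,
                    n_exact: int | None = None) -> SeqRecord:
    """Substitute each position independently with probability ``d`` to a
    uniformly chosen *different* residue.  With ``n_exact`` given, mutate at
    exactly that many (seeded) positions instead (count-exact mode)."""
    if not (0 <= d < 1):
        raise ValueError("d must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    alphabet = AA20 if rec.moltype == "aa" else NT4
    seq = list(rec.seq)
    n = len(seq)
    if n_exact is not None:
        positions = rng.choice(n, size=n_exact, replace=False)
    else:
        positions = np.nonzero(rng.random(n) < d)[0]
    for i in positions:
        alternatives = [c for c in alphabet if c != seq[i]]
        seq[i] = alternatives[rng.integers(len(alternatives))]
    return SeqRecord(id=rec.id, seq="".join(seq), description=rec.description,
                     genome_id=rec.genome_id, moltype=rec.moltype)


def mutate_at(rec: SeqRecord, substitutions: dict[int, str]) -> SeqRecord:
    """Deterministic substitutions at 1-based positions."""
    seq = list(rec.seq)
    for pos, res in substitutions.items():
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"position {pos} out of range")
        if seq[pos - 1] == res:
            raise ValueError(f"position {pos} already {res}")
        seq[pos - 1] = res
    return SeqRecord(id=rec.id, seq="".join(seq), description=rec.description,
                     genome_id=rec.genome_id, moltype=rec.moltype)


def _identity_quick(a: str, b: str) -> float:
    """Ungapped identity over the shorter sequence (generator-side check)."""
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def _new_family_ancestor(rng: np.random.Generator, length: int,
                         existing: list[str], max_retries: int = 50) -> str:
    """Draw a random protein kept below 40% quick-identity to all existing
    ancestors (rejection sampling with a retry cap)."""
    for _ in range(max_retries):
        cand = random_protein(rng, length)
        if all(_identity_quick(cand, e) < 0.40 for e in existing):
            return cand
    raise RuntimeError("could not draw a sufficiently novel family ancestor")


def _encode_protein(rng: np.random.Generator, protein: str, gc: float) -> str:
    """Reverse-translate with synonymous-codon choice biased toward the
    target GC percentage (applied mostly at wobble positions)."""
    target = gc / 100.0
    codons = []
    for aa in protein:
        opts = _CODONS[aa]
        gcs = np.array([(c.count("G") + c.count("C")) / 3.0 for c in opts])
        w = np.exp(-8.0 * np.abs(gcs - target))
        w /= w.sum()
        codons.append(opts[rng.choice(len(opts), p=w)])
    return "".join(codons)


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list(NT4), size=length, p=probs))


def simulate_pangenome(spec: SyntheticPangenomeSpec) -> SyntheticPangenome:
    """Generate proteomes, companion nucleotide genomes, a star tree and a
    truth table for a pangenome with known core/accessory/unique structure.

    Accessory presence vectors are resampled until a family is present in
    at least 2 and at most G-1 genomes, so realised classes always match
    the emitted truth.  Star-tree branch lengths grow with the per-genome
    unique count, which makes unique-vs-distance monotone by construction;
    a zero-length anchor leaf keeps nearest distances strictly ordered.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genomes
    if G < 1:
        raise ValueError("n_genomes must be >= 1")
    genome_ids = [f"g{i+1:02d}" for i in range(G)]
    lo, hi = spec.protein_length_range
    uniq_counts = spec.unique_counts()

    ancestors: dict[str, str] = {}
    family_class: dict[str, str] = {}
    presence: dict[str, list[str]] = {}
    existing: list[str] = []

    for i in range(spec.n_core):
        fam = f"core{i:04d}"
        ancestors[fam] = _new_family_ancestor(rng, int(rng.integers(lo, hi + 1)),
                                              existing)
        existing.append(ancestors[fam])
        family_class[fam] = "core"
        presence[fam] = list(genome_ids)

    for i in range(spec.n_accessory):
        if G < 3:
            break  # accessory (2..G-1 genomes) impossible below 3 genomes
        fam = f"acc{i:04d}"
        ancestors[fam] = _new_family_ancestor(rng, int(rng.integers(lo, hi + 1)),
                                              existing)
        existing.append(ancestors[fam])
        family_class[fam] = "accessory"
        while True:
            mask = rng.random(G) < spec.accessory_presence_p
            if 2 <= mask.sum() <= G - 1:
                break
        presence[fam] = [g for g, m in zip(genome_ids, mask) if m]

    for gi, g in enumerate(genome_ids):
        for i in range(uniq_counts[gi]):
            fam = f"uni_{g}_{i:03d}"
            ancestors[fam] = _new_family_ancestor(
                rng, int(rng.integers(lo, hi + 1)), existing)
            existing.append(ancestors[fam])
            family_class[fam] = "accessory" if G == 1 else f"unique:{g}"
            presence[fam] = [g]
    if G == 1:
        # degenerate case: every family is present in the single genome,
        # hence core by the partition rule
        family_class = {f: "core" for f in family_class}

    proteomes: dict[str, list[SeqRecord]] = {g: [] for g in genome_ids}
    gene_to_family: dict[str, str] = {}
    for fam in sorted(ancestors):
        anc = ancestors[fam]
        for g in presence[fam]:
            gene = f"{g}|{fam}"
            rec = SeqRecord(id=gene, seq=anc, genome_id=g, moltype="aa")
            rec = mutate_sequence(rec, spec.within_family_divergence, rng)
            proteomes[g].append(rec)
            gene_to_family[gene] = fam

    assemblies: dict[str, GenomeAssembly] = {}
    for g in genome_ids:
        parts = []
        for rec in proteomes[g]:
            parts.append(_encode_protein(rng, rec.seq, spec.gc_percent))
            parts.append(random_dna(rng, int(rng.integers(50, 151)),
                                    spec.gc_percent))
        rep = SeqRecord(id=f"{g}_chr", seq="".join(parts), genome_id=g,
                        moltype="nt")
        assemblies[g] = GenomeAssembly(genome_id=g, replicons=[rep])

    lengths = [0.1 + 0.05 * uniq_counts[i] + 0.001 * float(rng.random())
               for i in range(G)]
    tips = [f"{g}:{lengths[i]:.6f}" for i, g in enumerate(genome_ids)]
    tips.append("anchor:0.0")
    newick = "(" + ",".join(tips) + ");"

    truth = SyntheticTruth(
        gene_to_family=gene_to_family, family_class=family_class,
        expected_within_identity=100.0 * (1 - spec.within_family_divergence))
    return SyntheticPangenome(spec=spec, proteomes=proteomes,
                              assemblies=assemblies, truth=truth,
                              newick=newick)


def simulate_genome_pair(length_bp: int, d: float, gc: float = 50.0,
                         seed: int = 0, fragment_len: int = 1020,
                         ) -> tuple[GenomeAssembly, GenomeAssembly]:
    """A genome and a per-site mutated copy; expected ANI = 100 * (1 - d)."""
    if length_bp < 10 * fragment_len:
        raise ValueError("length_bp must be >= 10 * fragment_len")
    rng = np.random.default_rng(seed)
    a_seq = random_dna(rng, length_bp, gc)
    a = GenomeAssembly(genome_id="simA", replicons=[
        SeqRecord(id="simA_chr", seq=a_seq, genome_id="simA", moltype="nt")])
    b_rec = mutate_sequence(
        SeqRecord(id="simB_chr", seq=a_seq, genome_id="simB", moltype="nt"),
        d, rng)
    b = GenomeAssembly(genome_id="simB", replicons=[b_rec])
    return a, b


def simulate_lina_variants(base_length: int = 154, seed: int = 0,
                           divergences: dict[str, int] | None = None,
                           ) -> tuple[SeqRecord, dict[str, SeqRecord]]:
    """A base variant plus named references at exact mutation counts.

    ``divergences`` maps variant name -> number of substituted positions
    relative to the base sequence.
    """
    rng = np.random.default_rng(seed)
    base = SeqRecord(id="base", seq=random_protein(rng, base_length),
                     moltype="aa")
    divergences = divergences or {"type1": 2, "lina1": 15, "lina3": 10,
                                  "type3": 21}
    refs = {}
    for name, k in sorted(divergences.items()):
        refs[name] = SeqRecord(id=name,
                               seq=mutate_sequence(base, 0.0, rng, n_exact=k).seq,
                               moltype="aa")
    return base, refs
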