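"""Scaffold sequence design: De Bruijn-style k-mer uniqueness and FASTA I/O.

A good synthetic scaffold avoids internal secondary structure and staple
mis-hybridization.  The generator emits sequences in which every k-mer
(default order 8) occurs at most once and never equals the reverse
complement of any k-mer in the sequence (including itself), which bounds
self-complementarity and repetition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ScaffoldSequence:
    """A scaffold strand over a pure RNA (ACGU) or DNA (ACGT) alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        letters = set(self.residues)
        if not (letters <= set(RNA_ALPHABET) or letters <= set(DNA_ALPHABET)):
            bad = letters - set(RNA_ALPHABET + DNA_ALPHABET)
            raise ValueError(f"mixed or invalid scaffold alphabet: {sorted(bad)}")

    @property
    def length_nt(self) -> int:
        return len(self.residues)

    @property
    def is_rna(self) -> bool:
        return "U" in self.residues or "T" not in self.residues

    def as_rna(self) -> "ScaffoldSequence":
        return ScaffoldSequence(self.id, self.residues.replace("T", "U"))

    def as_dna(self) -> "ScaffoldSequence":
        return ScaffoldSequence(self.id, self.residues.replace("U", "T"))


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving the input alphabet (RNA or DNA)."""
    table = _RNA_COMPLEMENT if ("U" in seq or "T" not in seq) else _DNA_COMPLEMENT
    return seq.translate(table)[::-1]


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerViolation:
    position: int  # 1-based start of the offending k-mer
    kmer: str
    conflict_position: int
    conflict_kmer: str
    kind: str  # "repeat" or "reverse_complement"


def verify_kmer_uniqueness(sequence: str, order: int) -> list[KmerViolation]:
    """List all k-mer uniqueness violations (empty list = verified).

    A sequence is verified at a given order when every k-mer occurs exactly
    once and no k-mer equals the reverse complement of any k-mer in the
    sequence -- including itself, which rules out palindromic k-mers.
    """
    if len(sequence) < order:
        raise ValueError(f"sequence shorter than order {order}")
    seen: dict[str, int] = {}
    violations: list[KmerViolation] = []
    for i in range(len(sequence) - order + 1):
        kmer = sequence[i : i + order]
        if kmer in seen:
            violations.append(
                KmerViolation(i + 1, kmer, seen[kmer], kmer, "repeat")
            )
            continue
        rc = reverse_complement(kmer)
        if rc in seen:
            violations.append(
                KmerViolation(i + 1, kmer, seen[rc], rc, "reverse_complement")
            )
        elif rc == kmer:
            violations.append(
                KmerViolation(i + 1, kmer, i + 1, kmer, "reverse_complement")
            )
        if kmer not in seen:
            seen[kmer] = i + 1
    return violations


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def max_feasible_length(order: int) -> int:
    """Counting bound on verified sequence length at a given order.

    Each of the L - k + 1 windows consumes a k-mer and blocks its reverse
    complement, so at most 4^k / 2 windows fit.
    """
    return 4**order // 2 + order - 1


def generate_de_bruijn_scaffold(
    length_nt: int, order: int = 8, seed: int = 0, id: str | None = None
) -> ScaffoldSequence:
    """Generate a verified RNA scaffold by randomized greedy extension.

    The sequence is grown one base at a time; candidate bases are tried in
    a seed-shuffled order and the generator backtracks when no base keeps
    the k-mer set (and its reverse complements) collision-free.  Output is
    deterministic for a fixed seed and always passes
    :func:`verify_kmer_uniqueness` at the requested order.
    """
    if length_nt < order:
        raise ValueError(f"length_nt={length_nt} shorter than order={order}")
    if length_nt > max_feasible_length(order):
        raise ValueError(
            f"length {length_nt} infeasible at order {order}: at most "
            f"4^{order}/2 = {4**order // 2} distinct reverse-complement-"
            f"disjoint k-mers exist, capping length at "
            f"{max_feasible_length(order)} nt"
        )
    rng = random.Random(seed)
    used: set[str] = set()  # k-mers consumed, including reverse complements
    seq: list[str] = []
    # per-position shuffled candidate stacks for backtracking
    stacks: list[list[str]] = []

    def candidates() -> list[str]:
        c = list(RNA_ALPHABET)
        rng.shuffle(c)
        return c

    kmers: list[str] = []  # k-mer committed at each position >= order-1
    while len(seq) < length_nt:
        if len(stacks) <= len(seq):
            stacks.append(candidates())
        placed = False
        while stacks[len(seq)]:
            base = stacks[len(seq)].pop()
            if len(seq) + 1 < order:
                seq.append(base)
                placed = True
                break
            kmer = "".join(seq[-(order - 1) :]) + base
            rc = reverse_complement(kmer)
            if kmer in used or rc == kmer:
                continue
            seq.append(base)
            used.add(kmer)
            used.add(rc)
            kmers.append(kmer)
            placed = True
            break
        if placed:
            continue
        # dead end: backtrack one base
        if not seq:
            raise RuntimeError("backtracking exhausted; length infeasible")
        stacks.pop()
        dropped = seq.pop()
        del dropped
        if len(seq) + 1 >= order and kmers:
            k = kmers.pop()
            used.discard(k)
            used.discard(reverse_complement(k))

    result = "".join(seq)
    assert not verify_kmer_uniqueness(result, order)
    return ScaffoldSequence(id or f"debruijn_k{order}_n{length_nt}_s{seed}", result)


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed, 60-column wrapping)
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ScaffoldSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ScaffoldSequence(r.id, str(r.seq).upper()) for r in records]


def write_fasta(scaffolds: list[ScaffoldSequence] | ScaffoldSequence, path) -> None:
    if isinstance(scaffolds, ScaffoldSequence):
        scaffolds = [scaffolds]
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in scaffolds
    ]
    SeqIO.write(records, str(path), "fasta")
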