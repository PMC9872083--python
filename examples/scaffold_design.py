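"""Generate and verify a De Bruijn-style RNA scaffold.

Every 8-mer in the generated sequence occurs once and never equals the
reverse complement of any 8-mer, bounding repeats and self-complementarity
-- useful when no natural scaffold of the right length is at hand.
"""

from rnaori.scaffold_gen import (
    generate_de_bruijn_scaffold,
    verify_kmer_uniqueness,
    write_fasta,
)

scaffold = generate_de_bruijn_scaffold(1218, order=8, seed=1)
violations = verify_kmer_uniqueness(scaffold.residues, 8)
print(f"generated {scaffold.length_nt} nt, id={scaffold.id}")
print(f"8-mer windows: {scaffold.length_nt - 7}, violations: {len(violations)}")

# prefixes of a verified sequence stay verified: the same 1218-nt sequence
# supplies the 660- and 924-nt scaffolds of the 55- and 77-bp tetrahedra
for n in (660, 924):
    v = verify_kmer_uniqueness(scaffold.residues[:n], 8)
    print(f"  first {n} nt -> {len(v)} violations")

write_fasta(scaffold, "debruijn_1218.fasta")
print("wrote debruijn_1218.fasta")
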