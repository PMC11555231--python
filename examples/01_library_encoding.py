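"""Model the NNK-encoded cyclic-peptide library.

Builds the mixed-length library design, inspects its length distribution and
encodable diversity, and shows how the reprogrammed genetic code translates
the initiator and a scanning-mode internal AUG.
"""

from cyclodisplay import (
    LibraryDesign,
    length_weights,
    make_codon_table,
    reverse_translate,
    theoretical_diversity,
)

design = LibraryDesign()  # the printed template with 6-12-mer NNK ratios
print("random-region length weights (n: probability):")
for n, p in length_weights(design).items():
    print(f"  {n}: {p:.5f}")

div = theoretical_diversity(design)
print(f"\nencodable stop-free peptide diversity: {div:.3e}")
print("exceeds the 1e12 members actually displayed:", div > 1e12)

main = make_codon_table("main_D")
scan = make_codon_table("scanning")
print("\ninitiator ATG (main_D):", main.translate_codon("ATG", initiator=True))
print("elongation ATG (main_D):", main.translate_codon("ATG"))
print("elongation ATG (scanning):", scan.translate_codon("ATG"),
      "  # Met is replaced by N-methyl-alanine in the scanning code")

dna = reverse_translate("RDHHYRHPKY")
print("\ndeterministic reverse translation of RDHHYRHPKY:", dna)
# Each weight is the molar fraction of library members with that random-region
# length; the diversity bounds how many distinct cyclic peptides the template
# can encode.
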