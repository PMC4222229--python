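"""From a coding SNV to candidate minor-antigen nonamers.

Annotates one nonsynonymous variant on a toy transcript, builds the
variant-centered padded peptide (8 reference residues per side), and
enumerates every 9-mer window containing the substituted residue.
"""

import allopotential as ap

cds = "ATG" + "GCTTGGAAACCGGATGAACTGTTCCGT" * 3 + "TAA"  # 28-residue toy protein
model = ap.TranscriptModel(
    transcript_id="TOY.t1", gene_id="TOY", chrom="chr1", strand="+",
    cds_segments=[(101, 100 + len(cds))], cds_sequence=cds,
)
print(f"protein ({len(model.protein_sequence)} aa): {model.protein_sequence}")

pos = model.genomic_position(14 * 3)  # first base of codon 15
variant = ap.GenomicVariant("chr1", pos, model.cds_sequence[14 * 3], "T")
consequence = ap.annotate_coding_consequence(variant, model)
print(
    f"variant {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} -> "
    f"{consequence.ref_aa}{consequence.protein_pos}{consequence.alt_aa} "
    f"({'synonymous' if consequence.synonymous else 'nonsynonymous'})"
)

padded = ap.build_padded_peptide(consequence, model)
print(f"padded peptide ({len(padded.sequence)}-mer, variant at {padded.variant_offset}): {padded.sequence}")

nonamers = ap.enumerate_nonamers(padded)
print(f"{len(nonamers)} sliding 9-mer windows cover the variant residue:")
for n in nonamers:
    print(f"  {n.sequence}  (variant at position {n.variant_pos})")
print("Each window is one candidate ligand for HLA class I scoring.")
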