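"""Alanine masking of an alignment window for conformation-biased
structure prediction.

The residues of the target window (default 276-336, the TG2 segment whose
co-evolutionary signal pins the closed conformation) are replaced with
alanine across the alignment, removing that signal before prediction.
The target here is a short synthetic stand-in; guard letters verify the
window boundaries before anything is rewritten.
"""

from tg2screen.msa import Alignment, mask_msa_alanine

aln = Alignment(
    ids=["target", "homolog_1", "homolog_2"],
    seqs=["MKQWLCVDGH",
          "MRQWLCIDGH",
          "MKQ-LCVEGH"])

masked = mask_msa_alanine(aln, "target", start_res=3, end_res=6,
                          expected_start="Q", expected_end="C")

for sid, before, after in zip(aln.ids, aln.seqs, masked.seqs):
    print(f"{sid:10s} {before}  ->  {after}")

print("\nColumns mapped to target residues 3-6 (guarded as Q...C) are now "
      "alanine in every sequence; gaps are untouched, and the alignment "
      "shape is unchanged. On the real 687-residue target the same call "
      "with the defaults masks the 61-column window 276-336.")
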