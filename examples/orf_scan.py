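"""Scan a transcript for ORFs with canonical and near-cognate start codons.

Candidate transcripts from EST mining are often predicted non-coding yet
contain short ORFs; allowing near-cognate (non-AUG) initiation can reveal
longer products than the best AUG-starting frame.
"""

from est2tse import CANONICAL_STARTS, NEAR_COGNATE_STARTS, longest_orf, scan_orfs

# A toy transcript: a short AUG ORF up front, then a longer CTG-initiated
# ORF downstream (the situation where alternative initiation matters).
transcript = (
    "GGACG" + "ATG" + "GAAGGT" * 10 + "TAA"          # AUG ORF, 21 aa
    + "CCT" + "CTG" + "GCTGAA" * 25 + "TGA" + "AAC"  # CTG ORF, 51 aa
)

for label, starts in [("canonical (AUG)", CANONICAL_STARTS),
                      ("near-cognate", NEAR_COGNATE_STARTS)]:
    orfs = scan_orfs(transcript, starts, min_aa=10)
    best = longest_orf(transcript, starts, min_aa=10)
    print(f"{label:17s}: {len(orfs)} ORF(s) >= 10 aa; "
          f"longest {best.aa_length} aa, start {best.start_codon} "
          f"at {best.start} (frame {best.frame})")

# The near-cognate scan finds every canonical ORF plus the CTG-initiated
# one, whose peptide begins with M by the initiator convention.
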