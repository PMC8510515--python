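"""Landmark-relative numbering of a single receiver domain.

Builds a CheY variant carrying two Skn7-like markers (Cys at DD+17, Ser at
T+1), aligns it to the reference and prints the five landmark positions plus
a few named positions resolved on the query's own coordinates.
"""

from recprofiler import (
    align_to_reference,
    assign_landmarks,
    extract_positions,
    landmark_confidence,
    load_reference,
)

model = load_reference()
seq = list(model.sequence)
seq[29] = "C"   # DD+17 (reference index 30)
seq[87] = "S"   # T+1 (reference index 88)
query = "".join(seq)

aln = align_to_reference(query, model)
assignment = assign_landmarks(aln, model)
conf = landmark_confidence(aln, assignment, model)

print("alignment score:", aln.score)
print("typical:", assignment.typical, "| missing:", set(assignment.missing) or "-")
for lm in ("dd1", "dd2", "d", "t", "k"):
    print(f"  {lm:>3}: query index {assignment.indices[lm]:>3} "
          f"residue {assignment.residues[lm]} ({conf[lm]})")

positions = extract_positions(query, assignment)
for name in ("DD", "DD+1", "DD+17", "T+1", "K-3"):
    print(f"  {name:>6} -> {positions[name]}")

# The landmark indices are the query's own 1-based coordinates; DD+17 = C and
# T+1 = S are the two planted markers, K-3 = Y is CheY's own aromatic switch
# residue, untouched by the edits.
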