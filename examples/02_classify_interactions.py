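"""Classify drug-drug / drug-enzyme candidates with the band rules.

Runs the rule classifier on the eight published worked examples and on a
hand-built candidate, showing how fold-change/p-value bands (in vivo),
Ki bands (in vitro), and language cues combine.
"""

from pkddi import InteractionCandidate, QuantEvidence, classify
from pkddi.synthetic import table9_records

print("Worked examples:")
for rec_id, candidate, printed in table9_records():
    got = classify(candidate)
    status = "ok" if got == printed else "MISMATCH"
    print(f"  {rec_id:12s} ({candidate.entity_a}, {candidate.entity_b})"
          f" -> {got:5s} [printed {printed}] {status}")

# A hand-built in vivo candidate: AUC doubled, clearly significant.
cand = InteractionCandidate(
    "ketoconazole", "midazolam",
    quant=(QuantEvidence("AUC", "fold_change", 2.0, 0.003, "lt"),))
print()
print(f"(ketoconazole, midazolam) AUC x2.0, p<0.003 -> {classify(cand)}")

# The label is DDI because the fold change exceeds 1.50 with p below
# 0.05; between 0.67 and 1.50 the same evidence would read ADDI
# (significant but small) or NDDI (neither significant nor large).
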