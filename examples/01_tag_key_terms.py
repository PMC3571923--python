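"""Tag the six key-term classes in a PK sentence.

Drugs and metabolites come from the bundled probe-drug lexicon, enzymes
from the CYP name pattern, PK parameters from the parameter ontology, and
numbers/mechanisms/changes from the guideline word patterns.
"""

from pkddi import builtin_lexicon, tag_all

sentence = ("Itraconazole significantly increased the AUC(0-48) of "
            "paroxetine by 1.5 fold (P≤0.01) through CYP3A4 inhibition, "
            "while norverapamil was unaffected.")

lex = builtin_lexicon()
print(sentence)
print()
for term in tag_all(sentence, 0, lex):
    extra = ""
    if term.value is not None:
        extra = f" value={term.value}" + (f" unit={term.unit}"
                                          if term.unit else "")
    if term.is_pvalue:
        extra += f" p-value ({term.p_relation})"
    if term.parent:
        extra += f" parent={term.parent}"
    print(f"  [{term.span.start:3d},{term.span.end:3d}) "
          f"{term.category:13s} {term.span.text!r} -> "
          f"{term.normal_form}{extra}")

# Each line is one non-overlapping span: the category, the surface text,
# and the normalized form the relation rules consume (e.g. AUC(0-48)
# collapses to the ranked parameter AUC; norverapamil is recognized as a
# metabolite of verapamil and excluded from candidate pairing).
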