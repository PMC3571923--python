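"""Train and evaluate the all-paths graph-kernel DDI extractor.

Generates a synthetic annotated corpus, builds one combined
dependency/part-of-speech graph per candidate drug pair (entities
anonymized, metabolites removed, enzymes pairable), trains a support
vector machine on the precomputed normalized kernel matrix, and reports
precision/recall/F on a held-out document-level split.
"""

from pkddi import extractor
from pkddi.synthetic import GenConfig, generate_corpus

docs, tally = generate_corpus(GenConfig(n_documents=50, seed=7))
instances = extractor.instances_from_corpus(docs)
positives = sum(inst.gold for inst in instances)
print(f"{tally['total_sentences']} sentences, {len(instances)} candidate "
      f"pairs ({positives} true interactions)")

result = extractor.train_and_eval(instances, test_fraction=0.25, seed=7)
for split, report in (("train", result.train_report),
                      ("test", result.test_report)):
    print(f"  {split:5s} precision={report.precision:.3f} "
          f"recall={report.recall:.3f} f={report.f_measure:.3f} "
          f"(tp={report.tp} fp={report.fp} fn={report.fn})")

# The classifier sees only anonymized graphs — lexical and syntactic
# context, never the drug identities — so a high held-out F-measure means
# the planted interaction phrasing itself is being recognized.
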