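"""Corpus I/O: annotated XML, unified extraction XML, HTML, statistics.

Generates a small annotated corpus, round-trips it through the corpus XML
schema, converts it to the unified entity/pair layout, renders the colored
HTML view, and prints the frequency table.
"""

from pathlib import Path

from pkddi import corpus_io
from pkddi.synthetic import GenConfig, generate_corpus

out = Path("scratch/example_corpus")
out.mkdir(parents=True, exist_ok=True)

docs, _ = generate_corpus(GenConfig(n_documents=8, seed=2))

corpus_path = out / "corpus.xml"
corpus_io.write_corpus_xml(docs, corpus_path)
assert corpus_io.read_corpus_xml(corpus_path) == docs  # lossless
corpus_io.to_unified_xml(docs, out / "unified.xml")
corpus_io.render_html(docs, out / "corpus.html")
print(f"wrote {corpus_path}, unified.xml and corpus.html")

stats = corpus_io.corpus_stats(docs)
print("\nkey-term frequencies:")
for category, count in stats["terms"].items():
    print(f"  {category:13s} {count}")
print("sentence labels:", stats["sentences"])
print("pair relations:", stats["relations"])
print("candidate pairs in DDI sentences:", stats["total_pairs"])

# total_pairs counts every unordered pair of pairable entities within
# CDDIS/VDDIS sentences — the denominator of the extraction task.
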