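"""Show how classification noise degrades category recovery gracefully.

At zero noise the classifier recovers every generator-intended category; at
noise p, a fraction p of citations lose the abstract and MeSH terms the text
heuristics rely on, so recovery falls — but never below 1 - p.
"""

import evicite as ev

for noise in (0.0, 0.1, 0.3):
    spec = ev.random_corpus_spec(5, n_products=3, mean_citations=150)
    spec.classification_noise = noise
    corpora, truth = ev.generate_corpora(spec, return_truth=True)
    outcomes = [
        out.category is truth[out.record.local_id]
        for corpus in corpora
        for out in ev.classify_corpus(corpus)
    ]
    recovery = sum(outcomes) / len(outcomes)
    print(f"noise {noise:.1f}: recovery {recovery:6.1%} over {len(outcomes)} citations "
          f"(bound: >= {1 - noise:.0%})")

print(
    "\nNoise makes records ambiguous (a systematic review stripped of its"
    "\nabstract falls back to narrative review) rather than steering them to"
    "\na specific wrong category, so recovery stays above the bound."
)
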