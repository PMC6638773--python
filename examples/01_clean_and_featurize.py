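"""Clean a raw post stream and build compound feature vectors.

Generates a small contaminated corpus (duplicates, retweets, bot posts,
URLs), runs the cleaner, then featurises one post to show the compound
vector: n-gram counts plus word-class counts, sentiment counts and the two
emoji/emoticon binaries.
"""

from symptweet import (
    CorpusSpec,
    build_vector,
    build_vocabulary,
    clean_corpus,
    generate_corpus,
    load_lexicons,
    tokenize,
)

tweets, ann = generate_corpus(CorpusSpec(n_tweets=300, seed=42))
cleaned, report = clean_corpus(tweets)

print("cleaning report:")
for key, val in report.to_dict().items():
    print(f"  {key:24s} {val}")
print("-> every removed post was an injected duplicate/retweet/bot,")
print(f"   so {report.n_output} of the {len(ann['base_ids'])} genuine posts survive.\n")

lex = load_lexicons()
vocab = build_vocabulary([tokenize(t.text, lex) for t in cleaned], n_range=(1, 2), min_doc_freq=2)
print(f"vocabulary: {len(vocab)} n-grams (document frequency >= 2)")

text = "my asthma attack is awful tonight 😷"
vec = build_vector(text, vocab, lex)
print(f"\nfeature vector for: {text!r}")
for name, value in sorted(vec.items()):
    if value:
        print(f"  {name:20s} {value}")
print("-> 'wc:' counts come from the word-class lexicon, 'sent:' from the")
print("   positive/negative dictionaries, 'tone:' flags laughter and")
print("   negative emojis; the classifier consumes this mapping directly.")
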