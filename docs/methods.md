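# Methods

This note records the modelling and engineering decisions behind `cidrex`:
what the system computes, the defaults and why, what the synthetic generator
does and does not emulate, and the numerical conventions.

## Task and data model

A *document* is one article (title + abstract) with gold chemical/disease
mentions carrying MeSH concept ids, and a set of gold chemical-induced
disease (CID) relations at the concept level. A *candidate instance* is one
(chemical id, disease id) pair co-occurring in one article, labelled positive
iff annotated. The *knowledge base* maps a pair to a subset of
{`marker/mechanism`, `therapeutic`, `inferred`}; `null` is a padding type,
never stored. Offsets are 0-based half-open over `title + " " + abstract`
(the PubTator convention).

Conventions chosen where the underlying resources are ambiguous:

* composite mention ids (`D1|D2`) split into separate mentions sharing a
  span; unmapped ids (`-1`) are kept as mentions but never form candidates —
  this maximises recall without inventing identifiers;
* all ids are normalised identically on every read path (strip `MESH:`,
  uppercase), so corpus, knowledge table and tree table agree on keys;
* in knowledge tables, an empty direct-evidence field means `inferred`,
  mirroring the structure of curated chemical–disisease dumps.

## Preprocessing

Numbers without letters become `NUM`. Mentions are replaced by type-prefixed
id tokens; the candidate pair's mentions are additionally bracketed
(`ch_start ch_d014148 ch_end`). Replacement runs left-to-right on a rebuilt
string, so offsets never go stale; overlapping mention spans keep the longer
span (logged). Sentence splitting is a deterministic rule (sentence ends at
`.!?` + whitespace); it will over-split around abbreviations, which is
acceptable for the corpora targeted here and keeps the pipeline dependency
free. The title is sentence index 0 for span computation and is *also*
encoded separately as the theme vector.

PoS tagging is a pluggable interface; the bundled default is a deterministic
suffix-rule tagger (the original system's patched CoreNLP is neither
available nor necessary for the architecture to function). Marker and id
tokens always receive the reserved tag `ENT`.

Candidate pairs whose closest mentions are `K` or more sentences apart are
removed when the span filter is on: "within K consecutive sentences" is read
as admitting sentence-index distances 0..K−1 (K = 4 default). The filter is
applied to dev/test sets only by default; gold positives it removes are kept,
flagged `filtered`, and counted as false negatives at evaluation — they
contribute to POS and can never be true positives.

## Model

Dimensions at the reference defaults: word ℓ₁ = 100, PoS ℓ₂ = 10 (token
representation ℓ = 110), knowledge m = 200, grid n₁ = 30 sentences × n₂ =
120 words, CNN window w = 5 with f = 300 filters, BLSTM widths 220 and 440
*concatenated* — read as per-direction h₁ = 110 and h₂ = 220, since the
stated widths equal the input dimensions. Hence
dim(A′) = 2h₂ + f + 2h₁ = 960.

Numerical conventions:

* padding: the PAD embedding row is zero; masked LSTM steps carry the
  previous state, so an all-pad sentence encodes to the zero vector and
  padding can never influence a result; documents shorter than one CNN
  window are zero-padded to w rows;
* truncation keeps the head of over-long sentences/articles;
* attention scores are scaled by 1/m; `max` aggregation returns the
  *unweighted* embedding row at argmax α, ties toward the lower index; the
  classifier breaks probability ties toward the negative class;
* β₁ = β₂ = 1 (learnable weighting was reported unhelpful; fixed here);
* the `null` padding relation participates in attention as a real fourth
  type;
* initialisation is uniform(−0.05, 0.05) with LSTM forget-gate biases at 1;
  min_count = 1 vocabularies; both are common practice and seed-controlled;
* the title encoder has its own parameters (sharing with the sentence
  encoder is untested and off);
* dropout (rate 0.5) is applied to the sentence-encoder output (the input
  of both the document BLSTM and the CNN) and to the classifier input D_s —
  "LSTM and softmax layers"; recurrent-state dropout is not used;
* training: RMSprop (ρ = 0.9, ε = 1e−6, lr 0.001), batch 8, default 30
  epochs with best-dev-F checkpointing when a dev set is given. With a
  fixed seed, runs are bit-reproducible (init, shuffling and dropout all
  derive from the config seed).

Because the target environment has no deep-learning framework, the network
runs on a package-internal reverse-mode autodiff engine over float64 numpy
arrays (`cidrex.autograd`). Its operation set is exactly what the model
needs; every gradient rule is checked against central finite differences in
the test suite, and the attention/aggregation/convolution/softmax paths are
additionally cross-checked against independent brute-force oracles.

## Post-filter and evaluation

A positive prediction (c, dᵢ) is demoted iff another disease in the same
article has a MeSH tree number that strictly extends one of dᵢ's at a dot
boundary (any depth, not only direct children) and dᵢ has no mention inside
the title span. Mere presence of the more specific disease suffices; it need
not itself be predicted positive. Metrics are P = 100·TP/(TP+FP),
R = 100·TP/POS, F = 2PR/(P+R), reported to one decimal, overall and per
stratum (intra ⇔ minimum sentence distance 0); degenerate denominators give
0.

## Synthetic generator

The generator emulates the *structure* of an annotated abstract corpus:
titles, sentence sequences of filler tokens, entity mentions with
MeSH-like synthetic ids (`D9xxxxx`), gold relations, a knowledge table and
a tree-number table, all byte-reproducible from a seed. Two label signals
are controllable:

* `knowledge_signal` — probability that a positive pair carries
  `marker/mechanism` (occasionally plus `inferred`) and a negative carries
  `therapeutic` or nothing; at 0 the table is drawn independently of labels;
* `text_signal` — probability that the trigger token `induced` is placed
  adjacent to the pair's chemical mention iff the pair is positive; filler
  vocabulary never contains the trigger.

`inter_fraction` (default 0.3, matching the roughly one-third share of
inter-sentential relations in the real corpus) forces that share of
positives to never co-occur in a sentence, with sentence gaps of 1–3.
`positive_rate` defaults to 0.5; sentence/entity counts default to 3–6
sentences and 2–4 entities per article, which keeps articles in the shape of
short abstracts while remaining fast. With more than one pair per article
the signals can interact (a trigger planted for one pair sits near another);
the signal-recovery experiments therefore state their world as one chemical
and one disease per article (`entities_per_doc=(2, 2)`), where the
trigger ⇔ label equivalence is exact.

The generator does **not** emulate linguistic realism: no grammar, no
abbreviations, no coreference, no mention-boundary ambiguity, no composite
ids. A green signal-recovery test therefore establishes that the
architecture and training loop can extract a planted knowledge-base or
lexical signal at document level — not that the system reaches any
particular accuracy on real biomedical text.

The hypernym-case generator builds articles containing a chemical, a
specific disease and its tree ancestor, with the ancestor in the title in
every even-numbered article, so the expected demotion set is known in closed
form.

## Experiments at reduced widths

The signal-recovery experiments (and the acceptance script) run the model at
h₁ = h₂ = 16, f = 16, m = 8, ℓ₁ = 16, ℓ₂ = 4, 15 epochs on a 300-article
corpus — small enough for minutes of CPU, large enough that both the
knowledge path (held-out accuracy ≥ 0.9 with attention concentrated on
`marker/mechanism` for positives) and the text path (≥ 0.9 with the
knowledge vector zeroed) demonstrably work. The reported per-type attention
weight is the mean per-slot weight a type receives *when present* in the
pair's relation sequence, which is what attention-value inspection examines;
summing over the up-to-three duplicated `null` padding slots would make the
padding look dominant by construction.

## Known limitations

* Training is pure-python/numpy and single-threaded: full-width training
  (h₁ = 110, h₂ = 220, f = 300 over 30×120 grids) is possible but slow; the
  package is tuned for reduced-width CPU experiments.
* The rule-based sentence splitter and suffix tagger are crude
  approximations of the original tooling; both are injectable.
* Reproducing published corpus-level scores requires the BioCreative V CDR
  corpus, a curated chemical–disease dump and pretrained embeddings, none of
  which can ship with the package; loaders for all three formats are
  provided and tested on synthetic stand-ins.
* Whether sentence truncation, relation-slot ordering and CNN padding match
  the original system exactly is unknowable from its description; the
  conventions above are fixed and documented instead.
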