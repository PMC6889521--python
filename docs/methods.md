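# Methods

## Problem and pipeline

`bbrex` classifies intra-sentence (bacteria, location) mention pairs as
positive or negative *Lives_In* relations. The pipeline is:

1. **Ingestion** (`corpus_io`). Standoff annotations use 0-based,
   half-open character offsets; every mention surface is validated against
   the text slice on load. Discontinuous mentions are normalized to their
   covering span (the model consumes contiguous token spans).
   Dependency parses are accepted only as CoNLL-U; XPOS substitutes when
   UPOS is missing, and multiword-token / empty-node lines are skipped.
   Parses are aligned to the raw text left-to-right by token surface,
   which yields character spans per token; a token absent from the text is
   an error, since that parse cannot belong to the document.
2. **Candidate generation** (`candidates`). Each mention maps to the
   minimal token span covering its character extent; mentions straddling
   sentence boundaries are dropped with a warning. One instance is emitted
   per same-sentence bacteria × location pair. Mention spans collapse to
   single blinded tokens *before* graph construction, so the SDP endpoint
   is the entity node itself and the path-anchoring ambiguity of
   multi-word mentions never arises; the blinded token inherits the POS of
   the mention's first original token. Relative distances are computed on
   the blinded sequence as `l = entity_position − token_position`, the
   sign convention fixed by the worked example in which a token 4
   positions after the bacteria and 1 before the location scores (−4, 1).
   The dependency graph is undirected with unit edge weights; the SDP is
   found with Dijkstra, ties broken toward the lexicographically smallest
   index sequence so preprocessing is bit-reproducible across platforms.
   Pairs with no path are dropped and counted; pairs whose mentions
   overlap (in characters or in covering tokens) are skipped and counted;
   the counters reconcile exactly with the pair enumeration, and
   inter-sentence gold relations are counted separately so evaluation can
   charge them as false negatives.
3. **Representation** (`representations`). Token vector
   `z = [word (+PE on SDP) ; pos ; dist1 ; dist2]`. Defaults: word 200
   (400 for contextual providers), POS 100, distance 150 per entity — the
   printed total of 300 is read as the concatenation [dist1 ; dist2], 150
   per entity, since the two entities are symmetric; PE dimension equals
   the active word dimension. Distance embeddings initialize every
   component to tanh(l/s); distances beyond ±s clip to the boundary; the
   distance and POS tables are trainable after initialization (they are
   "initialized", not frozen). PE is the standard fixed sinusoid scheme
   and applies identically to static and contextual word vectors.
   Out-of-vocabulary words under the static provider receive a random
   vector drawn once from a generator keyed by (seed, word) — cached,
   query-order independent, and stable across processes. A deterministic
   hash provider serves as the no-download test fallback, and a
   contextual provider is a callable contract (token sequence → per-token
   vectors) with shape validation; pre-training such a provider is out of
   scope.
4. **Encoders** (`encoders`). The Entity-Oriented weights multiply each
   token's full embedding by `a_i · M` (weight × sequence length) so the
   expected magnitude of the sequence is preserved; they are applied after
   the embedding layer, before the BLSTM. The BLSTM concatenates forward
   and backward states (2 × 64 by default). In the Multi-Head encoder the
   per-query attention aggregates over keys (the summation index is read
   as standard self-attention); head outputs are concatenated and linearly
   projected back to the model dimension so the residual addition is
   dimension-consistent; the score denominator is √m with m the
   word-embedding dimension (not the per-head key dimension). SDPs pad to
   a fixed length (default 10; the BB corpus averages ≈ 4.8 SDP tokens) —
   longer paths truncate symmetrically around the midpoint, keeping both
   entity endpoints. Padding vectors are zero, masks exclude padding from
   every softmax and from max-pooling, and masked positions contribute
   zero vectors to the final per-position concatenation, so features are
   invariant to padding content (property-tested). The final SDP feature
   follows the per-position concatenation reading; mean-pooling would be a
   defensible alternative but is not implemented.
5. **Classifier and training** (`training`). The concatenated feature maps
   directly through one affine layer to the softmax (no hidden layer by
   default, matching the stated form; ReLU is used inside the CNN path).
   Dropout 0.5 applies to the concatenation only during training. Loss is
   cross-entropy (categorical when more than two classes are configured,
   so multi-class corpora such as drug–drug interaction data are
   supported by the classifier, though their corpus handling is out of
   scope); probabilities in the scalar loss contract clamp to
   [1e−7, 1−1e−7]. Optimization is minibatch Adam, lr 0.001, batch 4.
   Early stopping monitors development F1 with patience 2 (a patience
   value is not prescribed anywhere; 2 keeps the typical stopping epoch in
   the 3–5 range observed at full scale). A development set with no
   positives logs a warning and scores 0. Missing feature blocks shrink
   the classifier's weight matrix rather than contributing zeros.
   Checkpoints are zip archives of named float64 arrays plus the three
   config blocks as JSON, written with fixed timestamps so two runs with
   equal seeds produce byte-identical files.

## Synthetic data

The generator emulates the corpus shape the pipeline expects: standoff +
CoNLL-U documents, 1–3 sentences of 8–14 tokens, one bacteria and 1–2
location mentions per sentence, a closed POS set {NN, VB, IN, JJ, DT}, and
valid dependency trees (every non-root token governed by an earlier token,
checked as n−1 edges + connectivity). A cue verb (default `inhabits`)
occurs in *every* sentence; a pair is positive iff the cue lies on the
entity–entity SDP, which is decided by the location's attachment (under
the cue vs. under the root) with probability 0.5, giving ≈ balanced
classes. Labels flip with probability `label_noise` (default 0). Because
the cue is always present in the surface sentence, the rule is invisible
to a bag-of-words model and linearly visible on the SDP — passing the
end-to-end recovery test therefore demonstrates that the SDP branch, the
blinding, and the graph machinery work together, not that the model
handles real biomedical syntax: the generator reproduces none of the
lexical ambiguity, parse errors, coordination structures or inter-sentence
phenomena of PubMed text, so synthetic ceiling performance says nothing
about corpus-scale F1.

Two hand-built fixture documents encode canonical worked examples: the
*Helicobacter pylori* sentence with one bacteria and two locations (two
candidates whose blinded strings are asserted verbatim) and a
*mycobacteria*/Queensland-style sentence in which the probe token "in"
sits 4 tokens after the bacteria and 1 before the location yet off the
SDP. Both parses are hand-written, plausible Stanford-style attachments.

## Problem sizes

Unit tests run reduced dimensions (word 16–32, POS 4–8, distance 4–8 per
entity, BLSTM 8–16) on 60–300 instances; the end-to-end recovery check
trains the full architecture on 300 train / 100 test instances for 5
epochs at word 32. These sizes are the package's chosen desk-scale study
conditions; the paper-scale defaults (200/100/150, BLSTM 64) remain the
configuration defaults and are exercised for shape correctness.

## Numerical choices

* All arithmetic is float64 on a tape-based reverse-mode autograd; max-
  pooling routes gradients to the first maximizer on ties.
* Softmax is computed with a constant shift (max subtraction); training
  uses the log-softmax form directly.
* Masked attention scores receive −1e30 before the softmax rather than
  being removed, keeping shapes static.
* Forget-gate biases initialize to 1; other weights are Glorot-uniform;
  POS tables are N(0, 0.1); distance tables follow the tanh rule above.
* Welch's (unequal-variance) two-sided t-test is used for model
  comparison — the safer default when variances are not known to be
  equal; two degenerate zero-variance samples give t=0, p=1 by convention.
* The SD of the seed protocol is the sample SD (n−1).

## Known limitations

* Inter-sentence relations are not extracted — they are only counted as
  false negatives, so recall is bounded above on corpora that contain
  them.
* The official online scorer is not available offline; the internal
  scorer mirrors its pair-matching semantics and is the package's
  evaluation surface.
* Contextual word/sentence representations are provider contracts with
  deterministic fallbacks (hash vectors, zero sentence embeddings), not
  trained language models.
* Entity normalization (NCBI taxonomy, OntoBiotope) and parsing are out
  of scope; parse quality is taken as given.
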