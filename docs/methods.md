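# Model and methods

`agreemark` simulates a population of agents that plays pairwise reference
games about abstract objects and, through invention, social learning and
lateral-inhibition alignment, self-organizes a shared system of grammatical
agreement markers.  This note documents the model, its parameters, the
design choices made where the design was genuinely open, and what the
simulations do and do not show.

## The world

A run starts from a randomly generated ontology: `n_attributes` attributes
(default 5) with `n_values` mutually exclusive values each (default 3), and
`n_types` object types (default 10).  A type allows a uniformly drawn
subset of 1–5 attributes, each restricted to a uniformly drawn subset of
1–3 values.  A situation model holds 3 objects: each samples a type
uniformly and then exactly one allowed value per type attribute (one value
per attribute is a configurable choice; it makes "distinctive combination"
well defined).  The situation is shared verbatim by speaker and hearer, so
all uncertainty lives in the utterance.  Topics are subsets of 1–3 objects,
size uniform.

Identifiers are stable strings (`a`, `a-1`, `t-3`, `o-2`), and ontologies,
situations and vocabularies serialize to JSON/TSV for replay.

## The vocabulary

For every type, every meaning combination of at most three of its
attributes (one allowed value each) receives exactly one word; combinations
shared between types get a single word.  The vocabulary therefore has no
synonyms and no homonyms — interpretation complexity comes from word
*combination* only.  Word forms are random pronounceable syllable strings
(1–2 onset consonants, 1–2 vowels, optional coda; 2–3 syllables; mean
length ≈ 7 characters).  At default parameters this yields vocabularies of
roughly 250–270 words, most of them three-attribute meanings.

## Production

For each topic object the speaker finds a *distinctive combination*: a
minimal-size property subset true of the object whose conjunction is false
of every other object (ties broken by seeded random choice; a dominated
object aborts the game as a degenerate situation).  Speakers then
*over-specify*: every remaining true property is added with probability
`elaboration_rate` (default 0.8).  Over-specification is deliberate — human
speakers are well documented to include redundant attributes in referring
expressions — and the default is calibrated so that utterance lengths come
out at roughly 25 / 25 / 25 / 15 / 5 % for 1–5 words, the regime the whole
model is built for.  Any superset of a distinctive set is still
distinctive, so over-specification never breaks reference.

The expressed set is covered by a minimal *number* of words whose full
meanings are true of the object; among minimal covers the largest total
coverage wins, remaining ties are seeded-random.  Tokens are uttered in
random order (word order carries no meaning); a marker, when present, is a
suffix rendered `word-marker`.

## Interpretation

The hearer parses all words (the vocabulary is shared), then enumerates
co-reference hypotheses: set partitions of the word tokens, generated in
canonical restricted-growth order.  The number of partitions of an n-word
utterance is the Bell number B(n) (exact integer recurrence); at the
model's utterance lengths the space is at most a few hundred hypotheses.
Three filters apply in order:

1. **Markers.**  Words carrying the same recognized marker must share a
   block; words carrying different markers must not.  Since markers are
   overt suffixes, every distinct marker form separates its words from
   differently-marked ones; a *repeated* unknown form additionally ties its
   words together.
2. **Selection restrictions.**  A block survives iff the union of its
   words' properties fits within a single type's possible properties.
3. **Situation grounding.**  Blocks must be injectively assignable to
   objects that satisfy all their properties (injectivity is a configurable
   choice: one distinctive word-set per topic object).

A *reading* is a (partition, assignment) pair.  The hearer points iff
exactly one reading survives; the game succeeds iff the pointed-at objects
are the topic.  Ambiguity (more than one reading) is a failure.

Speakers detect the need for markers by *re-entrance*: interpreting their
own planned, unmarked utterance.  Markers are flagged as needed when the
result is ambiguous or when more than `reentrance_threshold` (default 8)
hypotheses survive selection restrictions — a tolerance for combinatorial
search cost, not just for outright ambiguity.  Once an agent owns at least
one marker construction it marks routinely and skips the simulation.

## Marker strategies

All strategies share the score dynamics: each construction carries a score
σ ∈ [0, 1], new constructions start at σ₀ = 0.5, and after a game the
*hearer only* updates scores by interpolated lateral inhibition with
alignment rate γ (default 0.2):

    reinforce:  σ ← σ + γ(1 − σ)
    inhibit:    σ ← σ(1 − γ)

Selection always prefers the highest score with seeded-random tie-breaks.

**Formal markers.**  Inventory entries are bare forms.  The speaker
attaches one distinct marker per topic object, highest scores first,
inventing fresh 2–3-syllable forms for any shortfall.  The hearer adopts
unknown marker forms outright (suffix morphology makes markerhood overt; a
stricter adopt-only-if-repeated mode is available), reinforces every
appearing marker and inhibits all non-appearing ones.  This drives the
population to a shared three-marker system — three because topics have at
most three objects.

**Meaningful markers.**  A construction is an association (form, feature
matrix, score).  Feature matrices assign each attribute×value cell `+`, `−`
or open `?`; word matrices are meaning-derived (their determined cells are
*grounded*), marker matrices are conventional.  Matrices merge by cellwise
unification (failure on +/− clash is a value, not an exception).  Marker
selection demands a *family*: an attribute on which the topic objects take
pairwise different values, with a fitting marker per value; by default
markers express a single attribute-value pair (two-attribute families can
be enabled, and then one-feature markers dominate usage as they apply more
broadly).  When no family applies the speaker invents markers for a
distinctive attribute — preferring the candidate attribute that needs the
fewest new markers — or, if no attribute set is distinctive, leaves the
utterance unmarked.  Hearers induce matrices for unknown markers from the
same distinctiveness principle; every licensed reading of the context
enters the inventory at σ₀ and lateral inhibition prunes the wrong guesses
(competitors are same-form/other-matrix and same-matrix/other-form
associations; only successful games align).

**Reuse.**  Identical to meaningful except invention: the speaker recruits
the existing word with the fewest properties that expresses the distinctive
feature(s).  Because that word is shared by the whole population, parallel
inventions collide on the same form, and hearers resolve a reused marker by
vocabulary lookup instead of guessing.

**Phonological reduction** (on top of reuse).  After the system stabilizes
(`reduction_start`, default game 2000), a speaker truncates a marker's
final character with probability R (default 0.1) unless the truncation
would collide with another marker's norm or stored variant (syncretism
guard) or empty the form.  A pending variant is produced 50/50 against the
norm.  Hearers recognize forms deviating by one trailing character; on the
second reception of a variant it becomes the new norm (voter dynamics), and
an abandoned longer form can be re-adopted the same way.  R is not
semantics-bearing; it was calibrated once so the full erosion (mean marker
length ≈ 7 → ≈ 4) completes within the 20,000-game horizon the reference
experiment uses, with communicative success unaffected.

**Coercion** (on top of reuse).  Vocabularies for coercion runs flag a
fraction of words as *controllers* (default 0.5); each word group must
contain one (covers are chosen accordingly; the widest word stands in when
none is available).  A controller's *agreement* matrix is a shared
convention partly decoupled from its meaning: half of the controllers keep
the meaning-derived matrix, the rest have grounded rows withheld with
probability 0.1, modelling features with no semantic grounding for that
word.  Marker choice is driven by the controllers' effective (highest
scoring) matrices: when a single-attribute family almost applies,
controllers open on that attribute are *coerced* — the marker's values are
assigned to them by convention, creating a controller variant that competes
by lateral inhibition; coercion over grounded or conflicting cells is
refused.  Populations start from a minimal shared system (markers for the
three values of one attribute).  Coercion lets agents serve most contexts
from very few families, roughly halving per-agent inventories relative to
plain reuse.

## Measures

Over a sliding window of w games (default 50; the window size matters
mostly for how quickly blips decay):

* **U(n, w)** — distinct marker forms used in the window.
* **V(n, w)** — 1 minus the mean agreement between the speaker's marker
  choice and the hearer's counterfactual choice for the same content,
  computed before the hearer's update.  The indicator is the fraction of
  marked groups that match (sets of forms for the formal strategy, whose
  markers are interchangeable across groups; per-group forms otherwise,
  with one-trailing-character tolerance under reduction).  Games without
  markers carry no indicator.
* **I(n)** — distinct marker forms introduced population-wide up to game n
  (inventions plus any seeded initial system).
* **E(n) = U(n, w)/I(n)** — efficiency: how well superfluous inventions
  were avoided.
* **P(n)** — cumulative agent replacements.  Turnover replaces one
  uniformly chosen agent with probability 5/1000 after each game
  (formal-strategy default; other experiments run without turnover); fresh
  agents know the vocabulary but own no markers.

Mean marker length is measured over marker *tokens* in the window — what is
actually uttered — because stored inventories retain long-dead losing forms.

## Reference experiment scales

The headline statistics (tests and `scripts/acceptance.py`) use: formal —
10 series × 1,000 games; meaningful and reuse — 10 series × 5,000 games,
no turnover; coercion vs reuse — 10 series × 1,000 games; reduction — 5
series × 20,000 games.  Series seeds derive deterministically from one
master seed, and matched comparisons (reuse vs de novo, coercion vs reuse)
share world seeds across arms.  Curve-level statistics (usage peak,
convergence game) are read off the cross-series mean curves; convergence is
the first post-peak game with mean U within half a marker of the optimum
and mean V ≤ 0.1 — under population turnover, per-series "stays converged
forever" detectors are dominated by whenever the last replacement happened
and say little about emergence time.

## Calibration, determinism, limitations

Three scalar parameters are not semantics-bearing and were fixed once
against the reference dynamics, then frozen: γ = 0.2 and the re-entrance
tolerance 8 (formal-strategy usage peak near game 50, shared system within
a few hundred games, long-run E ≈ 0.3), and the elaboration rate 0.8
(utterance-length distribution above).  σ₀ = 0.5 and w = 50 are
conventional midpoints.

Every stochastic step draws from a single seeded `random.Random` stream per
series, so runs are bit-reproducible; enumeration orders are canonical and
all tie-breaks flow through the seeded stream.

The generated world is deliberately abstract: attributes are unstructured
symbols (no perceptual grounding, no similarity structure), the vocabulary
is static and shared (no word learning, no synonymy/polysemy dynamics),
interaction is strictly dyadic with random pairing, and there is no
prosody, word order or repair dialogue.  About a quarter of games abort
because a topic object cannot be distinguished at all in its situation;
these count as failures and carry no utterance.  Consequences: passing
simulations show that the *strategies* suffice for the emergence,
transmission and streamlining of agreement systems under these idealized
conditions; they say nothing about grounded perception, about syncretism-
driven collapse of eroded systems (reduction stops at the syncretism
guard), or about semantic bleaching, none of which are modelled.
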