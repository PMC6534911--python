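# Methods

## The parsing model

Let `Σ` be the byte alphabet of the input text `T[0..n-1]` and pick a window
length `w ≥ 1`. A set `E ⊆ Σ^w` of *trigger strings* is extended to
`E' = E ∪ {#, $^w}`, where `#` and `$` are sentinels strictly below `Σ`.
Scanning `# T $^w`, a phrase runs from the start of one occurrence of an
element of `E'` to the end of the next. The dictionary `D` is the set of
distinct phrases; the parse `P` lists the occurrences by 0-based
lexicographic rank. Consecutive phrases overlap by exactly `w` symbols, each
phrase is longer than `w`, and each begins and ends with an element of `E'`
containing no other occurrence of one.

Two trigger policies are provided:

* **explicit-set** — membership of the window in a given `E` (used by the
  hand-checkable demo instance);
* **karp-rabin** — the window's polynomial hash is `0 (mod p)`, a
  content-defined rule in the spirit of rsync's rolling-hash slicing, which
  needs no stored `E` and gives expected phrase length ≈ `p`.

The driving facts, each of which is a tested property rather than an
assumption:

1. the set `S` of phrase suffixes longer than `w` is prefix-free;
2. every suffix of `# T $^w` longer than `w` has exactly one prefix in `S`;
3. sorting the suffixes of the parse sorts the corresponding text suffixes
   (order agreement at phrase starts).

Hence scanning the sorted groups of equal elements of `S` visits the text's
suffixes in BWT order, up to ties inside a group. A group whose string is a
proper suffix of exactly one phrase is preceded by one fixed character
everywhere, so it contributes a run of that character — frequency many
copies — with no parse information at all. Any other group (several source
phrases, or a suffix that is itself a complete phrase) is resolved by
merging the sources' inverted lists of BWT(P) positions in ascending order,
which by fact 3 is the text order of those occurrences: a proper-suffix
source contributes its fixed preceding character, a full-phrase source
contributes the *permuted last array* entry at the popped position (the `W`
character of the phrase preceding that occurrence in the text). Exactly one
emission carries the `#` sentinel — the one preceding the full text suffix —
and is rendered as the `$` terminator of the output BWT.

### The "easy" subsequence

The portion of the BWT that is determined without interleaving occurrences
within a group is exactly the set of groups to which a *single distinct*
character is mapped; the merge order inside such a group cannot change its
output. `easy_bwt_subsequence` emits those groups and placeholders (`-`)
elsewhere. On the demo instance only the group `TAC` — preceded once by `T`
and once by `A` — is placeholdered. (An alternative, stricter reading would
also placeholder every full-phrase group, since its characters come from
`W` rather than from the dictionary alone; the constant-emission rule is
the one that matches the subsequence the demo instance is checked against,
and it is the semantically sharp notion of "determined without the merge".)

## Conventions and edge cases

* **Sentinels.** Internally `# = 0x00` and `$ = 0x01`, so plain byte
  comparison realizes `# < $ < Σ`; ingest rejects texts containing either
  byte, naming the offending position. The relative order of the two
  sentinels never decides any comparison the algorithm performs (they are
  never the first differing byte pair of two compared strings — asserted by
  a test over random instances), so the assignment is a pure convenience.
* **Coordinates.** 0-based, half-open everywhere. The single deliberate
  exception is the `W` array definition "position `w+1` counted from the
  end", kept 1-based-from-the-end because that is how the quantity is most
  naturally stated: `W = phrase[len - (w+1)]`.
* **Scanning.** The first window is `T[0..w-1]`; windows never contain the
  prepended `#` and never extend into `$^w`. If the final `w` symbols of
  the text form a trigger, they begin the last phrase and `$^w` is appended
  to them. Back-to-back triggers are allowed and produce minimum-length
  (`w+1`) phrases. A text shorter than `w` parses into the single phrase
  `# T $^w`. The empty text is rejected.
* **Parse suffix convention.** With ranks shifted by +1 and a 0 terminator
  appended (an internal detail invisible to callers), the suffixes at
  indices `1..z` are sorted; the suffix of rank `j` names source phrase
  `P[t-1]` and permuted-last character `W[(t-2) mod z]`. The cyclic wrap
  `P[-1] = P[z-1]` makes the first parse suffix — the one for the `#`
  phrase — pick up the last symbol of the text, which is precisely the
  character preceding the lone terminator suffix in the BWT.
* **Hashing.** Polynomial hash with modulus `2^61 - 1` (Mersenne prime)
  for both the window hash and the phrase fingerprint. The multiplier is a
  large prime (27162335252586509), not the alphabet radix 256: with radix
  256 the hash residues modulo small trigger moduli remain correlated with
  individual window bytes on narrow alphabets — for DNA windows the value
  is never 0 mod 4, so a trigger modulus of 100 would never fire and the
  whole text would collapse into one phrase. The fingerprint additionally
  folds in the phrase length so that a leading `0x00` sentinel cannot
  alias. Phrase identity is always confirmed by full string comparison; a
  verified collision between distinct phrases aborts the parse with an
  error rather than attempting recovery. The trigger modulus `p` may be any
  integer ≥ 1 (`p = 1` degenerately makes every window a trigger). Both
  constants are exposed on `TriggerPolicy` for reproducibility.

## Suffix sorting

No external suffix-array library is assumed: suffixes of integer sequences
(the parse, and byte texts for the brute-force oracle) are sorted with a
numpy prefix-doubling (Manber–Myers) implementation, O(n log n) vectorized
sorting rounds. Dictionary-suffix groups are formed by directly sorting the
multiset of phrase suffixes longer than `w` — dictionaries are small
relative to the text, so the asymptotic refinements (induced sorting, LCP
grouping) would change constants, not outputs; the contract is validated
against a naive sort-all-suffixes oracle and, end-to-end, against the
direct BWT.

## Run-length FM-index

The BWT is stored as maximal runs (head symbol, length, start). `rank(c, i)`
is a binary search over the run starts of symbol `c` plus per-symbol
cumulative run lengths — contract-equivalent to a wavelet tree over run
heads with marking bitvectors, at the same O(log r) query cost. The `C`
array is built from the BWT histogram. `count` is standard backward search;
patterns containing a sentinel are rejected, absent symbols simply yield an
empty range.

The back-stepping SA sampler walks the LF permutation once around its
cycle, starting at row 0 — the row of the lone terminator suffix, whose
text position is `n` — and records (BWT position, text position) at run
starts and run ends only. The walk materializes a dense LF array (memory
linear in the text, unlike counting, which is linear in `r`); that is the
known cost of building the sample after the fact rather than during
construction. A walk that revisits a row or fails to close in exactly
`n + 1` steps raises a malformed-BWT error; the same walk underlies
`invert_bwt`.

## On-disk formats

The artifact bundle is four files plus a JSON sidecar: `.dict` (phrases in
lexicographic order, `#` stored as 0x01, `$` as 0x00, each phrase followed
by the terminator byte 0x01 — unambiguous because `#` can only be the very
first byte of the file and `$` only occurs in the final-in-text phrase's
tail), `.parse` and `.occ` (little-endian 4-byte unsigned integers), `.last`
(raw bytes), `.meta.json` (`w`, policy, `n`). Counts above `2^32 - 1`
are rejected by the writer. Reading validates truncation, rank range and
the parse/occ histogram, with distinct errors. BWT files store the
terminator as 0x00 (raw mode) or `$` (text mode).

## Synthetic collections

`synth_collection` emulates the repetitive structure of a genomic haplotype
collection at desk scale: a uniform random base sequence over {A,C,G,T} and
`copies − 1` variants with independent per-symbol substitutions (default
rate 0.01) and optional indels (off by default — substitution-only is the
simplest model of haplotype variants), concatenated in order and fully
deterministic per seed. It does **not** model realistic population
genetics, mutation spectra, rearrangements, N-runs or FASTQ artifacts, so
passing tests demonstrate correctness of the construction on repetitive
inputs, not biological fidelity. The generator is also how the index's
size behavior is exercised: with base length 10,000 and 1% substitutions,
the parsing footprint (dictionary bytes + 4 bytes per parse entry) at 100
copies is a much smaller fraction of the text than at 1 copy, and the BWT
run count grows far slower than the text as copies are added.

## Problem sizes used in the checks

The oracle-equivalence batch runs 500+ instances with text lengths up to
2,000 over alphabets of size 2, 4 and 20, windows 2–4, both trigger modes
and moduli {3, 5, 11, 31}; the structural-property batch uses lengths up to
200 where the checks are exhaustive over all suffixes. The RLFM check uses
a 10 kb × 100-copy collection (≈1 Mb) parsed with `w = 10, p = 100` — the
setting recommended for genome collections and the CLI default — with
1,000 patterns of lengths 1–30 and a full brute-force suffix array for
comparison at run boundaries. These sizes keep every oracle (including
naive counting and direct suffix sorting) exact and fast while exercising
all code paths; nothing in the implementation is specific to them.

## Known limitations

* Single-threaded, in-memory: no chunked/parallel parsing, no
  external-memory or two-pass merge, no streaming ingestion.
* Counting only: no locate queries; the SA sample is built and verified but
  not yet wired into a locate routine.
* The `.dict` format's disambiguation rule relies on the ingest guarantee
  that sentinels never occur inside the text.
* Fingerprint collisions abort the parse (probability ≈ z·|D| / 2^61); no
  recovery mechanism is provided.
* Text-mode BWT output renders the terminator as `$` and is therefore only
  unambiguous for texts not containing the literal `$` byte; raw mode has
  no such restriction.
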