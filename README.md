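# pfpbwt

Burrows–Wheeler Transform construction by **prefix-free parsing**, with a
counting-only **run-length FM-index** on top.

## The problem

Modern genomic collections — thousands of near-identical genomes or
haplotypes — are far too large to suffix-sort directly, yet they are highly
repetitive. `pfpbwt` exploits that repetitiveness: in one pass over the text
it slides a window of length *w* and cuts a phrase whenever the window's
Karp–Rabin hash is 0 modulo *p* (or whenever the window belongs to an
explicit trigger set *E*). Consecutive phrases overlap by exactly *w*
symbols, and the text — wrapped as `# T $^w` with sentinels below the
alphabet — is reduced to

* a **dictionary** *D*: the distinct phrases, lexicographically sorted, with
  their frequencies, and
* a **parse** *P*: the sequence of phrase ranks covering the text.

Because every suffix of a dictionary phrase longer than *w* belongs to a
prefix-free set *S*, and every text suffix longer than *w* begins with
exactly one element of *S*, sorting *S* partially sorts the text's suffixes.
`BWT(T$)` is then assembled from *D* and *P* alone, in workspace
proportional to their combined size — typically a small fraction of the
text for repetitive collections. A run-length encoded BWT with rank support
(the RLFM-index) answers `count` queries via backward search with the LF
mapping `LF(i) = rank_{BWT[i]}(i) + C[BWT[i]]`, in space proportional to the
number of BWT runs *r*, and a suffix-array sample at run boundaries can be
recovered post hoc by back-stepping through the LF permutation.

Intended users: anyone who needs BWTs or counting indexes of large
repetitive byte/DNA collections, and anyone studying BWT construction
algorithms who wants a compact, fully tested reference implementation with
brute-force oracles alongside.

## Worked example

```python
>>> import pfpbwt as pfp
>>> policy = pfp.TriggerPolicy.explicit(["AC", "AG", "T!"], w=2)
>>> result = pfp.parse_text(b"GATTACAT!GATACAT!GATTAGATA", policy)
>>> result.dictionary.displays
['#GATTAC', 'ACAT!', 'AGATA$$', 'T!GATAC', 'T!GATTAG']
>>> list(result.parse.ranks)
[0, 1, 3, 1, 4, 2]
>>> bwt = pfp.bwt_from_parse(result)
>>> pfp.bwt_to_text(bwt)
'ATTTTTTCCGGGGAAA!$!AAATATAA'
>>> index = pfp.RLFMIndex.from_bwt(bwt)
>>> index.r, index.count(b"GAT"), index.count(b"ACAT")
(13, 4, 2)
```

The five phrases are the distinct overlapping segments delimited by the
trigger windows (`#` and `$` are the sentinels); the parse lists their
lexicographic ranks in text order; the 27-symbol string is the BWT of
`GATTACAT!GATACAT!GATTAGATA$` (terminator printed `$`), whose 13 runs the
index stores; `GAT` occurs 4 times in the text and `ACAT` twice.

The same pipeline from a shell:

```sh
pfp synth --seed 1 --length 10000 --copies 50 --mut-rate 0.01 -o coll.fa
pfp bwt coll.fa -w 10 -p 100 -o coll.bwt
pfp index coll.bwt --from-bwt --sa-sample -o coll.npz
pfp count coll.npz patterns.txt
pfp selftest          # runs the worked example end-to-end
```

## Documentation

See `docs/methods.md` for the model, conventions, numerical choices and
limitations.
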