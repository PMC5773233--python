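# Refractive-error term lexicon: class label -> whole-word search terms.
#
# Matching is case-insensitive; a term matches only when flanked by
# non-letter characters, with "-" treated as letter-joining (so the
# hyphenated and fused spellings are separate terms). Edit or replace
# this file (see TermLexicon.from_yaml) to use a different vocabulary.
myopia:
  - myopia
  - myopic
  - near-sighted
  - near-sightedness
  - nearsighted
  - nearsightedness
hyperopia:
  - hyperopia
  - hyperopic
  - hypermetropia
  - hypermetropic
  - far-sighted
  - far-sightedness
  - farsighted
  - farsightedness
astigmatism:
  - astigmatism
  - astigmatic
ametropia_other:
  - ametropia
  - ametropic
  - refractive error
  - refractive errors
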