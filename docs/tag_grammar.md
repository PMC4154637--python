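# Sequence-tag grammar

A sequence tag is written as tokens, each one position, optionally
dash-separated:

```ebnf
tag      = token , { [ "-" ] , token } ;
token    = monomer , { group } ;
group    = "(" , monomer , { "/" , monomer } , ")" ;
monomer  = letter            (* one-letter code, any case *)
         | letter , letter , { letter } ;   (* lower-case name, e.g. "orn" *)
```

* A **dash-separated** tag may mix one-letter codes and NORINE-style
  names per token: `V-V-T(S)-T(S)-A-I(L)-V-G`, `thr-pro-pro-arg`,
  `V-allothr-I(L)`.
* An **undashed** tag is read as a run of one-letter codes, each
  optionally followed by parenthesized alternatives: `VHFVGWI(L)` is
  seven positions, the last one `{ile, leu}`.
* Parenthesized groups add alternative candidates to the preceding
  position; several alternatives are `/`-separated: `A(G/S)`.
* Token detection is per token: one character = one-letter code,
  longer = monomer name (case-insensitive). Unknown monomers,
  unbalanced parentheses and empty tokens are errors.

The canonical output form (`format_tag`) is dash-separated with the
alphabetically first candidate as the head, e.g. `ser(thr)`;
`parse_tag(format_tag(t))` reproduces `t`'s candidate sets exactly.

## Mass-shift input

A tag may instead be given as an ordered list of mass shifts in Da
(`--masses 99.068,113.084,...`). Each shift collects the union of
candidate monomers from all conversion-table rows within the tolerance
(default 0.02 Da, `--tolerance`); a shift matching no row is an error
naming the shift. Conversion tables are tab-separated
(`mass<TAB>cand1/cand2<TAB>label`) and user-replaceable; the shipped
NRP and RiPP tables are documented reconstructions (see
`docs/methods.md`).
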