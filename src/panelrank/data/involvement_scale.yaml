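name: involvement
levels:
- level: 1
  term: No involvement
  l: 1
  m: 1
  u: 1
- level: 2
  term: Low involvement
  l: 1
  m: 3
  u: 5
- level: 3
  term: Moderate involvement
  l: 3
  m: 5
  u: 7
- level: 4
  term: High involvement
  l: 5
  m: 7
  u: 9
- level: 5
  term: Specialist in the subject
  l: 7
  m: 9
  u: 9
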