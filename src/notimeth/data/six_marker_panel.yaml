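# Six-marker detection panel with the 2-of-6 decision rule.
k: 2
markers:
- NL1-CJ4R (C)
- NL6-FJ5R (C)
- NL3-CA11RS
- NLJ-003RD
- NL3003R (U)
- NRLA404R (U)
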