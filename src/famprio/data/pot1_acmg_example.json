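{
  "variant": "7:124503601:C>A",
  "gene": "POT1",
  "codes": ["PM2", "PP1", "PP3"],
  "expected_classification": "Uncertain significance",
  "note": "Illustrative worked example only: a plausible evidence-code set for a rare co-segregating missense variant with concordant in-silico support. Not asserted by any curation source."
}
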