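# Default configuration. Loading this file reproduces the built-in defaults.

# Canonical unit factors, in hours. Months are fixed at 30 days and years
# at 365 days for deterministic conversion.
unit_factors:
  second: 0.0002777777777777778
  minute: 0.016666666666666666
  hour: 1.0
  day: 24.0
  week: 168.0
  month: 720.0
  year: 8760.0

# Sample-title rule (b)(i): a single-letter candidate is a false time point
# when its magnitude appears within this many tokens of a count keyword in
# the summary or overall design.
keyword_window: 2
count_keywords: [sample, samples, patient, patients, subject, subjects]

# Relative tolerances: progression membership and canonical-value identity.
progression_rel_tol: 1.0e-6
dedupe_rel_tol: 1.0e-9

# Path to a Disease Ontology OBO file; empty means the bundled mini snapshot.
ontology_path: ""

output_format: jsonl
log_level: INFO
seed: 42
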