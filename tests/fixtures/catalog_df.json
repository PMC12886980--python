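{
  "comment": "hand-counted degrees of freedom per topology (shannon construct): df = p*(p*+1)/2 - n_free",
  "simplest_sem": {"n_observed": 12, "n_free": 28, "df": 50},
  "simple_sem": {"n_observed": 12, "n_free": 27, "df": 51},
  "complex_sem": {"n_observed": 21, "n_free": 63, "df": 168},
  "complex_path": {"n_observed": 10, "n_free": 46, "df": 9}
}
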