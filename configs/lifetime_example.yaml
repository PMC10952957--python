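# Lifetime-model overrides (defaults live in incentives_cea.lifetime.ModelParams).
# Example: undiscounted run with a larger PSA spread on intervention costs.
discount_rate: 0.0
intervention_cost_se:
  incentives: 20.0
  control: 10.0
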