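# Small smoke-test cohort; all other parameters keep the trial-calibrated
# defaults (471/470 per arm, seven sites, late-pregnancy quit 0.268/0.123).
n_incentives: 60
n_control: 60
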