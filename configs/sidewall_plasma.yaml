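# sidewall_plasma scenario with default physics; resolution and horizons can be
# overridden on the command line (clotflow run --config configs/sidewall_plasma.yaml)
scenario: sidewall_plasma
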