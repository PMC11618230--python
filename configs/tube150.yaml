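# tube150 scenario with default physics; resolution and horizons can be
# overridden on the command line (clotflow run --config configs/tube150.yaml)
scenario: tube150
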