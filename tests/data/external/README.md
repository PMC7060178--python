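Place the one-entry protein FASTA translating RefSeq NM_153840.2 here as
gpr110_NM_153840.fasta to enable the two sequence-dependent acceptance tests.
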