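# miRNA families reported as changing in both ethanol-treated mice and rats
mir-7
mir-9
mir-10
mir-15
mir-17
mir-26
mir-29
mir-30
mir-101
mir-130
mir-181
mir-204
mir-339
mir-340
mir-368
mir-434
mir-467
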