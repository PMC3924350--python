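# miRNA families reported as changing in both ethanol-treated mice and human alcoholics
let-7
miR-7
miR-15
miR-101
miR-140
miR-152
miR-17
miR-34
miR-135
miR-144
miR-146
miR-301
miR-339
miR-368
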