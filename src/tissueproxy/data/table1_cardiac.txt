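# Cardiac arrhythmia genes not expressed in heart (median TPM < 1.5)
KCNE2
KCNE5
SCN10A
SEMA3A
SCN3B
KCNE1
KCND2
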