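sample	band_lengths	source
F3	2100;3500	gel
F5	5000	gel
F7	3500	gel
F9	3500	gel
F10	3000	gel
F11	3000	gel
F13	3500	gel
F15	3000	gel
F16	3500	gel
F17	2500;3500	gel
F19	3500	gel
F20	2500	gel
F21	2100	gel
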