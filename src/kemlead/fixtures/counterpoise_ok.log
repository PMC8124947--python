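 Synthetic counterpoise log (emitted by kemlead, no QM program was run).
 Counterpoise: doing DCBS calculation, full system.
 Counterpoise corrected energy =      -152.510000000
 Counterpoise: BSSE energy =         0.002000000
 Counterpoise: raw complexation energy =       -0.012000000 Hartree
 Counterpoise: corrected complexation energy =       -0.010000000 Hartree
 Normal termination of synthetic log.
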