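>SERF_synthetic synthetic stand-in for the 68-residue yeast SERF protein; matches published composition constraints (net charge +12, nine Arg, one Pro, ERDK-rich, helical CTR) but is NOT the wild-type sequence
MARGNQKDNAKKMEQNLKGKRKRNPSGTVKRDDKHGSEEALRKLEEEKRKEKAELLRKMA
REKGAKRS
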