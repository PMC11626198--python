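>TAR HIV-1 TAR apical stem-loop fragment, 29 nt
GGCAGAUCUGAGCCUGGGAGCUCUCUGCC
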