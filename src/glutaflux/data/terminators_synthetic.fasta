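>T7term synthetic stand-in terminator (hairpin + U-tract architecture; NOT the phage T7 terminator sequence)
TAGCATAACCCCTTGGGGCCTCTAAACGGGTCTTGAGGGGTTTTTTG
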