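# Transmembrane generic-number ranges shared across class A receptors.
# Note TM7 skips 7x44: positions are restricted to those for which the
# network stays connected under node-coupling deletion.
1x36-1x56
2x40-2x63
3x24-3x54
4x42-4x61
5x38-5x60
6x34-6x57
7x36-7x43
7x45-7x55
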