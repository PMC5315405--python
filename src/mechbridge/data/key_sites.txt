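# Known key functional sites of class A GPCRs (Tehan et al. survey):
# highly conserved positions along the orthosteric-site -> G-protein
# pathway. Used as the positive set for ROC validation; edit freely.
1x50
2x46
2x50
3x40
3x43
3x50
4x50
5x50
5x58
6x30
6x40
6x41
6x44
6x48
6x50
7x49
7x50
7x53
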