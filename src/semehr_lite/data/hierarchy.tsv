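# child	parent (is-a)
C0019158	C0023895
C0019196	C0019158
C2148557	C0019196
C0220847	C0019196
C2711227	C0019158
C0151766	C0023895
C0348754	C0151766
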