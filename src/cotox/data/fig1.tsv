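taxon	f1	f2	f3	f4	|	t1
a	0	+	0	+	|	-
b	-	-	+	-	|	0
c	-	+	0	0	|	+
d	+	0	-	+	|	0
e	+	0	-	0	|	0
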