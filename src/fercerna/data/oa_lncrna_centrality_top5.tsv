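metric	node	value
degree	AC011511.5	4
degree	AC087284.1	3
degree	AC012615.1	2
degree	AL358072.1	2
degree	C9orf139	2
betweenness	C9orf139	17.45
betweenness	MIR155HG	41.1
betweenness	AC087284.1	41.41
betweenness	AC011511.5	56.67
betweenness	AL358072.1	115.32
closeness	AL358072.1	13.25
closeness	C9orf139	13.25
closeness	AC012615.1	13
closeness	AC011511.5	12.28
closeness	AC009812.1	11.83
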