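# Optional structural-annotation overrides, keyed by composition label.
# Columns: label, class, antennarity, bisected, fucosylated.
# Rows here win over the composition -> structure rule set, for analytes
# where orthogonal structural evidence contradicts the default reading.
# The packaged default is empty: the rule set covers the shapes of the
# shipped 68/70-analyte panels.  Add rows as
#   H6N5F1	complex	3	false	true
label	class	antennarity	bisected	fucosylated
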