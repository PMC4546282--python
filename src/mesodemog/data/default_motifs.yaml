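# Illustrative, Phylotree-style diagnostic motifs for Native American mtDNA
# haplogroups, restricted to control-region positions. These are NOT asserted
# as real-world truth: they exist so that haplogroup calling has a default
# table to exercise, and every test of calling accuracy plants these same
# motifs in simulated data. Replace with a curated table for real analyses.
A2: [16111T, 16223T, 16290T, 16319A, 146C, 153G, 235G]
B2: [16183C, 16189C, 499A]
B4b1: [16136C, 16183C, 16189C, 499A]
C1: [16223T, 16298C, 16325C, 16327T]
D1: [16223T, 16325C, 16362C]
D4h3a: [16223T, 16241G, 16301T, 16342C]
X2a: [16213A, 16223T, 16278T, 200G]
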