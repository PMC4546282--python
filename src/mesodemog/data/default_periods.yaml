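# Mesoamerican chronological periods in years before present (anchor 1950 CE).
# Boundaries follow the conventional chronology: Lithic/Archaic stage to
# 550 BCE-ish Preclassic boundary as used in the default analysis window;
# the Colonial boundary converts 1521 CE to 429 ybp.
- {name: Lithic, start_ybp: 15000, end_ybp: 2500}
- {name: Preclassic, start_ybp: 2500, end_ybp: 1750}
- {name: Classic, start_ybp: 1750, end_ybp: 1050}
- {name: Postclassic, start_ybp: 1050, end_ybp: 429}
- {name: Colonial, start_ybp: 429, end_ybp: 0}
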