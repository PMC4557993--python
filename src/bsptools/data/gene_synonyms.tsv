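symbol	canonical
LOC101107624	BSP5
BSP5L	BSP5
BSP-30 KDA LIKE	BSPH2
RSVP14	BSP1
RSVP20	BSP5
RSVP22	BSP5
LOC101105521	BSP3
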