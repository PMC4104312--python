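# Structural states of the major PIN clades on the reference cladogram.
# Interpretation of the published clade set: the seven lineages that depart
# from the canonical structure are the angiosperm clades PIN5, PIN6, PIN8,
# PIN9, PIN12 (PIN6/PIN12 semicanonical), the Physcomitrella PIND clade and
# the Marchantia PINW/PINX/PINY group treated as one lineage.
clade	state
BC	canonical
PIND	noncanonical
MpPIN_WXY	noncanonical
Lyco1	canonical
Lyco2	canonical
PIN5	noncanonical
PINI	canonical
PIN12	semicanonical
PINK	canonical
PINL	canonical
PINM	canonical
PINN	canonical
PIN6	semicanonical
PINJ	canonical
PINE	canonical
PINF	canonical
PING	canonical
PINH	canonical
PIN1	canonical
PIN9	noncanonical
PIN11	canonical
PIN2	canonical
PIN3	canonical
PIN8	noncanonical
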