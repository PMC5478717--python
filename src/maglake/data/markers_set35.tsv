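# Universal single-copy marker set, 35 genes.
# Content is user-replaceable; completeness arithmetic depends only on the set size.
rplA
rplB
rplC
rplD
rplE
rplF
rplK
rplL
rplM
rplN
rplP
rplS
rplT
rpmA
rpsB
rpsC
rpsE
rpsI
rpsJ
rpsK
rpsM
rpsS
rpsT
rpoB
rpoC
infC
pheS
pheT
secY
ffh
frr
nusA
pyrG
dnaG
tsf
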