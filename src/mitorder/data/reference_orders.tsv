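# Reference circular mitochondrial gene orders (aculiferan molluscs), version 1.
# One genome per line: id<TAB>provenance<TAB>comma-separated signed labels in
# plus-strand positional order; a leading "-" marks genes on the minus strand.
#
# provenance tags:
#   fixed        placement supported by published running text for that lineage
#   provisional  placement completed following the classic chiton arrangement
#                (Katharina tunicata); user-replaceable where lineage-specific
#                evidence is graphical only.  In the aculiferan/polyplacophoran
#                ancestor this concerns the trnT and trnP placements.
aculifera_ancestor	provisional:T,P	cox1,cox2,D,atp8,atp6,-F,-nad5,-H,-nad4,-nad4L,T,-S2,-cob,-nad6,P,-nad1,-L1,-L2,-rrnL,-V,-rrnS,-M,-C,-Y,-W,-Q,-G,-E,cox3,K,A,R,N,I,nad3,S1,nad2
polyplacophora_ancestor	provisional:T,P	cox1,cox2,D,atp8,atp6,-F,-nad5,-H,-nad4,-nad4L,T,-S2,-cob,-nad6,P,-nad1,-L1,-L2,-rrnL,-V,-rrnS,-M,-C,-Y,-W,-Q,-G,-E,cox3,K,A,R,N,I,nad3,S1,nad2
solenogastres_ancestor	fixed	cox1,cox2,atp8,D,atp6,T,P,-F,-nad5,-H,-nad4,-nad4L,-S2,-cob,-nad6,-nad1,-L2,-rrnL,-V,-rrnS,-M,-C,-Y,-W,-Q,-G,-L1,-E,R,K,I,cox3,A,N,nad3,S1,nad2
caudofoveata_ancestor	provisional:T,P	cox1,cox2,D,atp8,atp6,-F,-nad5,-H,-nad4,-nad4L,T,-S2,-cob,-nad6,P,-nad1,-L1,-L2,-rrnS,-M,-C,-Q,-Y,-rrnL,-V,-G,-W,E,cox3,K,A,R,I,S1,N,nad3,nad2
wirenia_argentea	fixed	cox1,cox2,atp8,D,atp6,T,P,-F,-nad5,-H,-nad4,-nad4L,-S2,-cob,-nad6,-nad1,-L2,-rrnL,-V,-rrnS,-M,-C,-Y,-W,-Q,-G,-E,-L1,-I,-K,-R,-N,-A,-S1,cox3,nad3,nad2
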