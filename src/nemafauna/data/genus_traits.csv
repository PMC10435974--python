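# Genus trait reference for soil nematode faunal analysis.
# trophic_group: Ba bacterivore, Fu fungivore, Pp plant parasite, Op omnivore/predator.
# cp_value: colonizer-persister score (Bongers 1990 conventions).
# fresh_weight_ug: plausible adult fresh body weight (Nemaplex-scale literature values).
# predator: 1 marks predatory taxa inside the merged Op group (used by the
#   structure-component guild assignment for c-p 2 predators).
genus,trophic_group,cp_value,fresh_weight_ug,predator
Rhabditis,Ba,1,2.0,0
Caenorhabditis,Ba,1,0.7,0
Protorhabditis,Ba,1,0.25,0
Mesorhabditis,Ba,1,0.6,0
Panagrolaimus,Ba,1,0.9,0
Acrobeloides,Ba,2,0.4,0
Acrobeles,Ba,2,0.9,0
Cephalobus,Ba,2,0.5,0
Eucephalobus,Ba,2,0.45,0
Chiloplacus,Ba,2,0.7,0
Cervidellus,Ba,2,0.3,0
Heterocephalobus,Ba,2,0.5,0
Plectus,Ba,2,0.8,0
Anaplectus,Ba,2,1.1,0
Wilsonema,Ba,2,0.15,0
Monhystera,Ba,2,0.35,0
Eumonhystera,Ba,2,0.2,0
Prochromadora,Ba,3,0.5,0
Alaimus,Ba,4,0.3,0
Aphelenchoides,Fu,2,0.15,0
Aphelenchus,Fu,2,0.3,0
Ditylenchus,Fu,2,0.25,0
Filenchus,Fu,2,0.3,0
Nothotylenchus,Fu,2,0.35,0
Tylencholaimus,Fu,4,0.5,0
Tylenchus,Pp,2,0.3,0
Psilenchus,Pp,2,0.5,0
Malenchus,Pp,2,0.2,0
Paratylenchus,Pp,2,0.15,0
Helicotylenchus,Pp,3,0.8,0
Pratylenchus,Pp,3,0.35,0
Rotylenchus,Pp,3,1.2,0
Criconemella,Pp,3,0.6,0
Longidorus,Pp,5,6.0,0
Tripyla,Op,3,1.5,1
Mylonchulus,Op,4,2.5,1
Anatonchus,Op,4,6.0,1
Eudorylaimus,Op,4,3.5,0
Mesodorylaimus,Op,4,1.8,0
Dorylaimus,Op,4,8.0,0
Thonus,Op,4,2.0,0
Discolaimus,Op,5,4.5,1
Oxydirus,Op,5,5.5,0
Aporcelaimus,Op,5,12.0,0
Aporcelaimellus,Op,5,9.0,0
Prodorylaimus,Op,5,7.0,0
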