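# Microbes significantly changed under an animal-based diet (gut microbiome
# diet-intervention study); one name per line. Species-rank entries first,
# then genus-rank entries. "Microbe MLG480" is a metagenomic linkage group
# with no formal species name; "Roseburia Eubacteriumrectale" is kept as
# printed in the source table.
Eubacterium biforme
Microbe MLG480
Actinobacillus porcinus
Alistipes finegoldii
Alistipes putredinis
Bacteroides coprocola
Bacteroides fragilis
Bacteroides salyersiae
Bifidobacterium adolescentis
Bifidobacterium gallicum
Bifidobacterium longum
Bilophila wadsworthia
Blautia producta
Clostridium bolteae
Clostridium orbiscindens
Collinsella aerofaciens
Dialister invisus
Faecalibacterium prausnitzii
Megasphaera elsdenii
Mitsuokella multacida
Parabacteroides johnsonii
Prevotella copri
Raoultella
Roseburia Eubacteriumrectale
Roseburia faecis
Ruminococcus bromii
Ruminococcus callidus
Ruminococcus flavefaciens
Ruminococcus gnavus
Alistipes
Akkermansia
Bacteroides
Bifidobacterium
Blautia
Catenibacterium
Clostridium
Coprococcus
Dialister
Escherichia
Eubacterium
Faecalibacterium
Lachnobacterium
Lachnospira
Odoribacter
Oscillospira
Parabacteroides
Phascolarctobacterium
Roseburia
Prevotella
Ruminococcus
Sutterella
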