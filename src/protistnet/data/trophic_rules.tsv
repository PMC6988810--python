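# Default group-level trophic conventions for coastal protist 18S surveys.
# Most-specific matching rank wins (species > genus > family > group).
taxon	rank	category
Bacillariophyta	group	autotroph
Mamiellophyceae	group	autotroph
Dinophyceae	group	mixotroph
Cryptophyceae	group	mixotroph
Chrysophyceae	group	mixotroph
Dictyochophyceae	group	mixotroph
Trebouxiophyceae	group	mixotroph
Chlorophyceae	group	mixotroph
Rhodophyta	group	mixotroph
Prymnesiophyceae	group	mixotroph
Ciliophora	group	heterotroph
MAST	group	heterotroph
Picozoa	group	heterotroph
Bicoecea	group	heterotroph
Cercozoa	group	heterotroph
Telonemia	group	heterotroph
Centroheliozoa	group	heterotroph
Syndiniales	group	parasite
Labyrinthulea	group	parasite
Oomycota	group	parasite
Perkinsea	group	parasite
Pirsonia	group	parasite
Noctiluca scintillans	species	heterotroph
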