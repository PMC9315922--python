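# IMGT amino-acid physicochemical classes (hydropathy / volume / chemical
# characteristics), transcribed from the IMGT Aide-memoire. One row per
# standard amino acid; each column is a partition of the 20 residues.
amino_acid	hydropathy_class	volume_class	chemistry_class
A	hydrophobic	very_small	aliphatic
C	hydrophobic	small	sulfur
D	hydrophilic	small	acidic
E	hydrophilic	medium	acidic
F	hydrophobic	very_large	aromatic
G	neutral	very_small	aliphatic
H	neutral	medium	basic
I	hydrophobic	large	aliphatic
K	hydrophilic	large	basic
L	hydrophobic	large	aliphatic
M	hydrophobic	large	sulfur
N	hydrophilic	small	amide
P	neutral	small	aliphatic
Q	hydrophilic	medium	amide
R	hydrophilic	large	basic
S	neutral	very_small	hydroxyl
T	neutral	small	hydroxyl
V	hydrophobic	medium	aliphatic
W	hydrophobic	very_large	aromatic
Y	neutral	very_large	aromatic
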