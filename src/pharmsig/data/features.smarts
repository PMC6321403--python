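# Default pharmacophore feature definitions: one "<label> <SMARTS>" per line.
# Labels: A = H-bond acceptor, D = H-bond donor, a = aromatic,
#         H = hydrophobic, P = positive centre, N = negative centre.
# This table is a synthetic reconstruction in the spirit of common open
# pharmacophore definition sets; it is NOT a verbatim copy of any published
# set and users with validated definitions should supply their own file.
# A multi-atom match is placed at the centroid of its matched atoms; the
# same fragment may carry several labels (e.g. aromatic rings are also
# hydrophobic), producing coincident feature points.

# H-bond acceptors: carbonyl/oxide O, hydroxyl and ether O, basic sp3 N,
# pyridine-type aromatic N.
A [OX1]
A [OX2;H1]
A [OX2;H0;!$(O=*)]
A [NX3;H0;v3;!$(N-*=[O,N,S]);!$(N-a)]
A [nX2;H0]

# H-bond donors: N-H (neutral or cationic), O-H, S-H, pyrrole-type N-H.
D [N;!H0;v3]
D [N;!H0;+1;v4]
D [OX2;H1;+0]
D [SX2;H1;+0]
D [n;H1]

# Aromatic rings (5- and 6-membered), placed at the ring centroid.
a a1aaaaa1
a a1aaaa1

# Hydrophobic: aromatic rings, gem-dimethyl branch points, methyls on
# carbon, halogens, thioether sulfur.
H a1aaaaa1
H a1aaaa1
H [C;D3,D4](-[CH3])-[CH3]
H [CH3;$([CH3]-[#6])]
H [Cl,Br,I]
H [SX2;$(S(-[#6])-[#6])]

# Positive centres: formally charged N, protonatable aliphatic amines.
P [N,n;+1]
P [NX3;H2;+0;$(N-[CX4])]
P [NX3;H1;+0;$(N(-[CX4])-[CX4])]
P [NX3;H0;+0;$(N(-[CX4])(-[CX4])-[CX4])]

# Negative centres: formally charged O/S, carboxylic and sulfonic acids.
N [O,S;-1]
N [CX3](=O)[OX2H1]
N [SX4](=O)(=O)[OX2H1]
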