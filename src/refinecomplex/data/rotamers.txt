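# Minimal backbone-independent rotamer library.
# Columns: residue chi1 chi2 chi3 chi4 probability ("." = no such chi).
# Probabilities sum to 1 per residue type.
ALA .    .    .    .    1.00
GLY .    .    .    .    1.00
PRO .    .    .    .    1.00
SER -65  .    .    .    0.45
SER 180  .    .    .    0.35
SER 65   .    .    .    0.20
CYS -65  .    .    .    0.50
CYS 180  .    .    .    0.30
CYS 65   .    .    .    0.20
THR -60  .    .    .    0.45
THR 60   .    .    .    0.40
THR 180  .    .    .    0.15
VAL 175  .    .    .    0.55
VAL -60  .    .    .    0.30
VAL 65   .    .    .    0.15
ILE -60  170  .    .    0.60
ILE 180  165  .    .    0.25
ILE -60  -60  .    .    0.15
LEU -65  175  .    .    0.55
LEU 180  65   .    .    0.30
LEU -85  65   .    .    0.15
ASP -70  -15  .    .    0.50
ASP 180  10   .    .    0.30
ASP 65   -10  .    .    0.20
ASN -65  -40  .    .    0.45
ASN 180  30   .    .    0.30
ASN 65   50   .    .    0.25
GLU -65  180  -10  .    0.40
GLU 180  180  0    .    0.35
GLU -60  -60  -20  .    0.25
GLN -65  180  -25  .    0.40
GLN 180  180  0    .    0.35
GLN -60  -60  -40  .    0.25
MET -65  180  75   .    0.35
MET -65  180  -75  .    0.35
MET 180  180  180  .    0.30
LYS -65  180  180  180  0.50
LYS 180  180  180  180  0.35
LYS -60  -60  180  180  0.15
ARG -65  180  180  90   0.40
ARG 180  180  180  180  0.35
ARG -60  180  180  -90  0.25
HIS -65  -70  .    .    0.40
HIS 180  60   .    .    0.35
HIS 65   -70  .    .    0.25
PHE -65  90   .    .    0.50
PHE 180  80   .    .    0.35
PHE 65   90   .    .    0.15
TYR -65  90   .    .    0.50
TYR 180  80   .    .    0.35
TYR 65   90   .    .    0.15
TRP -65  95   .    .    0.40
TRP 180  -105 .    .    0.35
TRP 65   90   .    .    0.25
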