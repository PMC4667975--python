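# Backbone-independent soft-rotamer library: modal chi-angle combinations with
# standard deviations and prior probabilities, in the style of the Dunbrack
# backbone-independent library. This is a compact synthetic stand-in table
# carrying representative modal values; substitute a full library by pointing
# the loader at another file with the same layout.
# columns: resname  prior  chi1_mean chi1_sd  [chi2_mean chi2_sd ...]
SER  0.48   62.0 10.0
SER  0.29  -65.0 10.0
SER  0.23  180.0 10.0
CYS  0.55  -65.0 10.0
CYS  0.26 -177.0 10.0
CYS  0.19   63.0 10.0
THR  0.49   62.0 10.0
THR  0.43  -60.0 10.0
THR  0.08 -175.0 10.0
VAL  0.73  175.0 10.0
VAL  0.20  -60.0 10.0
VAL  0.07   63.0 10.0
ILE  0.60  -65.0 10.0  170.0 12.0
ILE  0.25  -57.0 10.0  -60.0 12.0
ILE  0.15   62.0 10.0  170.0 12.0
LEU  0.59  -65.0 10.0  175.0 12.0
LEU  0.29 -177.0 10.0   65.0 12.0
LEU  0.12  -85.0 10.0   65.0 12.0
MET  0.30  -65.0 10.0  -65.0 12.0  -70.0 15.0
MET  0.25  -65.0 10.0  180.0 12.0   75.0 15.0
MET  0.25 -177.0 10.0  180.0 12.0   75.0 15.0
MET  0.20 -177.0 10.0   65.0 12.0   75.0 15.0
PHE  0.44  -65.0 10.0   90.0 12.0
PHE  0.33 -177.0 10.0   80.0 12.0
PHE  0.23   62.0 10.0   90.0 12.0
TYR  0.44  -65.0 10.0   90.0 12.0
TYR  0.33 -177.0 10.0   80.0 12.0
TYR  0.23   62.0 10.0   90.0 12.0
TRP  0.40  -65.0 10.0  100.0 12.0
TRP  0.35 -177.0 10.0 -105.0 12.0
TRP  0.25   62.0 10.0  -90.0 12.0
HIS  0.35  -65.0 10.0  -70.0 12.0
HIS  0.35 -177.0 10.0   65.0 12.0
HIS  0.30   62.0 10.0  -75.0 12.0
ASP  0.55  -70.0 10.0  -15.0 12.0
ASP  0.30 -177.0 10.0    5.0 12.0
ASP  0.15   62.0 10.0  -10.0 12.0
ASN  0.40  -65.0 10.0  -40.0 12.0
ASN  0.35 -177.0 10.0   -5.0 12.0
ASN  0.25   62.0 10.0  -75.0 12.0
GLU  0.40  -65.0 10.0  -65.0 12.0  -40.0 15.0
GLU  0.35 -177.0 10.0  180.0 12.0    0.0 15.0
GLU  0.25  -65.0 10.0  180.0 12.0  -10.0 15.0
GLN  0.40  -65.0 10.0  -65.0 12.0  -40.0 15.0
GLN  0.30 -177.0 10.0   65.0 12.0    0.0 15.0
GLN  0.30  -65.0 10.0  180.0 12.0  -25.0 15.0
LYS  0.40  -65.0 10.0  180.0 12.0  180.0 15.0  180.0 15.0
LYS  0.35 -177.0 10.0  180.0 12.0  180.0 15.0  180.0 15.0
LYS  0.25  -65.0 10.0  -65.0 12.0  180.0 15.0  180.0 15.0
ARG  0.35  -65.0 10.0  180.0 12.0  180.0 15.0  180.0 15.0
ARG  0.35  -65.0 10.0  -65.0 12.0  180.0 15.0  180.0 15.0
ARG  0.30 -177.0 10.0  180.0 12.0   65.0 15.0   85.0 15.0
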