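# Fixed snapshot of atomic masses bundled for bit-stable results.
# mono = mass of the most abundant isotope (CODATA/AME2020);
# avg  = IUPAC 2021 conventional standard atomic weight.
# element	mono	avg
H	1.00782503207	1.008
C	12.0	12.011
N	14.0030740048	14.007
O	15.9949146196	15.999
S	31.97207100	32.06
P	30.97376163	30.973761998
Na	22.9897692809	22.98976928
K	38.96370668	39.0983
Cl	34.96885268	35.45
Ca	39.96259098	40.078
Fe	55.9349375	55.845
Se	79.9165213	78.971
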