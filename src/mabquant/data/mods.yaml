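# Registry of named modification deltas (composition changes applied to a base
# composition).  Values are either a plain formula string (all counts positive)
# or an element -> signed-count mapping.
lysine: C6H12N2O                 # one C-terminal Lys residue, +128.095 Da mono
hexose: C6H10O5                  # one Hex residue (galactose), +162.053 Da mono
glycation: C6H10O5               # glucose adduct; isobaric with one hexose
fucose: C6H10O4                  # one dHex residue, +146.058 Da mono
neuac: C11H17NO8                 # one sialic-acid residue, +291.095 Da mono
hexnac: C8H13NO5                 # one HexNAc residue, +203.079 Da mono
pyro_glu: {H: -3, N: -1}         # N-terminal Gln -> pyroglutamate, -17.027 Da
deamidation: {H: -1, N: -1, O: 1}   # Asn -> Asp, +0.98402 Da mono
oxidation: {O: 1}                # Met/Trp oxidation, +15.995 Da mono
lc_truncation_qivls: {C: -25, H: -44, N: -6, O: -7}  # loss of LC N-terminal pentapeptide QIVLS, -540.327 Da mono
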