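# Idealized internal-coordinate parameters for ring substituent groups
# and ring heteroatom attachments.  Distances in Angstrom, angles in
# degrees.  Key grammar: <group>.<parameter> = <number>.
# Values are standard covalent-geometry defaults; override any of them
# by loading a user file with the same grammar on top of this one.

# hydroxyl
OH.d_CO = 1.43
OH.d_OH = 0.96
OH.a_OCC = 109.5
OH.a_HOC = 107.0

# fluoro
F.d_CF = 1.38
F.a_FCC = 109.5

# methyl
CH3.d_CC = 1.52
CH3.d_CH = 1.09
CH3.a_CCC = 111.0
CH3.a_HCC = 110.5

# methoxy
OCH3.d_CO = 1.43
OCH3.d_OC = 1.43
OCH3.d_CH = 1.09
OCH3.a_OCC = 109.5
OCH3.a_COC = 111.5
OCH3.a_HCO = 109.5

# hydroxymethyl
CH2OH.d_CC = 1.52
CH2OH.d_CO = 1.43
CH2OH.d_OH = 0.96
CH2OH.a_CCC = 111.0
CH2OH.a_OCC = 109.5
CH2OH.a_HOC = 107.0
CH2OH.d_CH = 1.09
CH2OH.a_HCC = 109.5

# amino
NH2.d_CN = 1.47
NH2.d_NH = 1.01
NH2.a_NCC = 109.5
NH2.a_HNC = 109.5

# plain hydrogen (valence filler)
H.d_CH = 1.09
H.a_HCC = 109.5

# ring heteroatom attachments
HET.d_NH = 1.01
HET.a_HNC = 109.5
HET.d_PH = 1.42
HET.a_HPC = 96.0
HET.d_BH = 1.19
HET.a_HBC = 120.0
HET.d_SO = 1.44
HET.a_OSC = 109.5
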