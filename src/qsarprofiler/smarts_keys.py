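"""Functional-group SMARTS key dictionary for the `smarts_keys` fingerprints.

An ordered mapping key-name -> SMARTS.  Bit i of a `smarts_keys` fingerprint
is set when pattern i matches the molecule at least once; the count variant
stores the number of distinct matches.  The dictionary is deliberately small
and fully documented — it is a similarity fingerprint, not a substructure
screen — and its order is frozen: changing it would silently change every
stored fingerprint.
"""

SMARTS_KEYS = {
    # element / hybridization keys
    "sp3_carbon": "[CX4]",
    "sp2_carbon": "[CX3]=[!#8]",
    "sp_carbon": "[CX2]#*",
    "aromatic_carbon": "c",
    "aromatic_nitrogen": "n",
    "aromatic_oxygen": "o",
    "aromatic_sulfur": "s",
    "halogen_f": "[F]",
    "halogen_cl": "[Cl]",
    "halogen_br": "[Br]",
    "halogen_i": "[I]",
    "phosphorus": "[#15]",
    "sulfur_any": "[#16]",
    "boron": "[#5]",
    "silicon": "[#14]",
    # oxygen functional groups
    "hydroxyl": "[OX2H]",
    "alcohol": "[CX4][OX2H]",
    "phenol": "c[OX2H]",
    "ether": "[OD2]([#6])[#6]",
    "aldehyde": "[CX3H1](=O)[#6,#1]",
    "ketone": "[#6][CX3](=O)[#6]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "carboxylate": "[CX3](=O)[O-]",
    "ester": "[#6][CX3](=O)[OX2H0][#6]",
    "carbonate": "[OX2][CX3](=O)[OX2]",
    "peroxide": "[OX2][OX2]",
    # nitrogen functional groups
    "primary_amine": "[NX3H2][CX4]",
    "secondary_amine": "[NX3H1]([CX4])[CX4]",
    "tertiary_amine": "[NX3H0]([CX4])([CX4])[CX4]",
    "aniline_nitrogen": "[NX3;!$(N=O)]c",
    "amide": "[NX3][CX3](=[OX1])",
    "nitrile": "[NX1]#[CX2]",
    "nitro": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "azo": "[#6]N=N[#6]",
    "imine": "[CX3]=[NX2]",
    "guanidine": "[NX3][CX3](=[NX2])[NX3]",
    "urea": "[NX3][CX3](=[OX1])[NX3]",
    # sulfur functional groups
    "thiol": "[SX2H]",
    "thioether": "[SX2]([#6])[#6]",
    "sulfoxide": "[$([SX3]=[OX1]),$([SX3+][OX1-])]",
    "sulfone": "[SX4](=[OX1])(=[OX1])",
    "sulfonamide": "[SX4](=[OX1])(=[OX1])[NX3]",
    "sulfonic_acid": "[SX4](=[OX1])(=[OX1])[OX2H]",
    # phosphorus
    "phosphate_like": "[PX4](=[OX1])",
    # rings and topology
    "ring_atom": "[R]",
    "aromatic_ring_atom": "[a;R]",
    "fused_ring_atom": "[R2]",
    "three_membered_ring": "[r3]",
    "spiro_or_bridge": "[X4;R2]",
    "benzene_ring": "c1ccccc1",
    # misc
    "trifluoromethyl": "[CX4](F)(F)F",
    "vinyl": "[CX3]=[CX3]",
    "alkyne": "[CX2]#[CX2]",
    "acyl_halide": "[CX3](=[OX1])[F,Cl,Br,I]",
    "epoxide": "[OX2r3]",
}
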