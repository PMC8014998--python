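"""Physical constants and static residue tables.

Monoisotopic atomic masses are IUPAC/CODATA values; average residue masses
are the standard values used for intact-protein (kDa-scale) mass display.
"""

# monoisotopic atomic masses, Da; 13C and D (2H) treated as distinct elements
ATOMIC_MONO = {
    "H": 1.0078250319,
    "D": 2.0141017780,
    "C": 12.0,
    "13C": 13.0033548378,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# residue (i.e. dehydrated) elemental compositions
RESIDUE_COMPOSITION = {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
}

# standard average residue masses, Da (ExPASy convention)
RESIDUE_AVERAGE = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

WATER_MONO = 2 * ATOMIC_MONO["H"] + ATOMIC_MONO["O"]  # 18.0105646
WATER_AVERAGE = 18.01528

# search-engine modification deltas expressed as net elemental compositions
MODIFICATION_COMPOSITIONS = {
    "dimethyl_light": {"C": 2, "H": 4},
    "dimethyl_heavy": {"13C": 2, "D": 6, "H": -2},
    "acetyl": {"C": 2, "H": 2, "O": 1},
    "pyroglu_E": {"H": -2, "O": -1},
    "pyroglu_Q": {"N": -1, "H": -3},
}

# bacterial N-end-rule classes of N-terminal residues
NEND_RULE_CLASS = {
    "A": "stabilizing", "S": "stabilizing", "T": "stabilizing",
    "G": "stabilizing", "M": "stabilizing", "V": "stabilizing",
    "I": "stabilizing", "C": "stabilizing", "P": "stabilizing",
    "H": "stabilizing",
    "D": "secondary_destabilizing", "E": "secondary_destabilizing",
    "N": "secondary_destabilizing", "Q": "secondary_destabilizing",
    "L": "destabilizing", "F": "destabilizing", "W": "destabilizing",
    "Y": "destabilizing", "R": "destabilizing", "K": "destabilizing",
}
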