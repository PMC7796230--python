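"""Physical constants, element tables, and RBP presets.

Units throughout the package: kcal/mol (energy), Å (length), K (temperature),
amu (mass), e (charge), fs (time).
"""

from __future__ import annotations

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872041

#: Coulomb constant, kcal Å mol^-1 e^-2 (vacuum).
COULOMB_CONSTANT = 332.0637

#: 1 kcal/mol expressed in amu Å^2 fs^-2 (converts forces to accelerations).
KCAL_PER_MOL_IN_AMU_A2_FS2 = 4.184e-4

#: van der Waals radii (Å) used for solvent-accessible surface area.
ELEMENT_VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: Average atomic masses (amu).
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

#: Formal charge per residue name at neutral pH (His neutral by default).
RESIDUE_FORMAL_CHARGES = {
    "ARG": +1,
    "LYS": +1,
    "ASP": -1,
    "GLU": -1,
}

#: Atom counts (including hydrogens) of mid-chain charged residues in the
#: CHARMM36m topology, used to convert a residue selection to an atom count.
CHARGED_RESIDUE_ATOM_COUNTS = {
    "ARG": 24,
    "LYS": 22,
    "ASP": 12,
    "GLU": 15,
}

#: The 12-rung solute-temperature ladder used for ribose binding protein (K).
#: Shipped verbatim as an explicit preset; the spacing follows no closed-form
#: generation rule.
LADDER_RBP12 = (
    300.00, 318.11, 337.11, 357.10, 378.07, 400.11,
    423.25, 447.60, 473.14, 499.97, 528.13, 550.00,
)

#: Domain definition of ribose binding protein (1-based inclusive ranges).
RBP_DOMAIN_RANGES = {
    "ntd": ((1, 100), (236, 259)),
    "ctd": ((108, 231), (269, 271)),
    "hinge": ((101, 107), (232, 235), (260, 268)),
    "ntd_base": ((99, 100), (236, 237), (258, 259)),
    "ctd_base": ((108, 109), (230, 231), (269, 270)),
}

#: The 22 surface charged residues selected as the gREST_SSCR solute region of
#: the G134R mutant of ribose binding protein, with selection provenance:
#: residues near the domain interface (criterion i), charged hinge residues
#: (criterion ii) and the neutrality completion set (criterion iii).
RBP_SOLUTE_RESIDUES = {
    67: ("ASP", "interface"),
    69: ("ASP", "interface"),
    89: ("ASP", "interface"),
    90: ("ARG", "interface"),
    104: ("ASP", "hinge"),
    110: ("LYS", "neutrality"),
    118: ("LYS", "neutrality"),
    134: ("ARG", "interface"),
    139: ("ARG", "interface"),
    140: ("GLU", "interface"),
    141: ("ARG", "interface"),
    163: ("ASP", "interface"),
    166: ("ARG", "interface"),
    168: ("LYS", "interface"),
    192: ("GLU", "interface"),
    215: ("ASP", "interface"),
    219: ("ASP", "interface"),
    221: ("GLU", "interface"),
    243: ("LYS", "neutrality"),
    260: ("LYS", "hinge"),
    264: ("ASP", "hinge"),
    266: ("LYS", "hinge"),
}
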