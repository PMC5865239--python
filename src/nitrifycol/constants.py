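"""Physical constants and unit conversions used throughout the package.

Every piece of arithmetic that converts between culture-measurement units
(protein, cells, nmol) and model units (mol N m^-3, day) goes through the
values in this table, so the bookkeeping is auditable in one place.

Notes
-----
Nitrogen is fixed at 14 g/mol (not 14.007): the published culture-derived
quantities this package reproduces (e.g. a 0.12 fmol N cell^-1 quota from
10.2 fg protein at 16% N) were computed with 14, and consistency with those
printed values matters more here than the fifth significant digit.
"""

#: Atomic masses (g mol^-1)
N_G_PER_MOL = 14.0
C_G_PER_MOL = 12.0

#: Default nitrogen mass fraction of protein (g N per g protein).
PROTEIN_N_FRACTION = 0.16
#: Plausible range used for uncertainty analyses.
PROTEIN_N_FRACTION_RANGE = (0.10, 0.20)

HOURS_PER_DAY = 24.0
SECONDS_PER_DAY = 86400.0

#: Concentration conversions. Internal model unit is mol N m^-3.
#: 1 umol L^-1 (uM) = 1e-6 mol / 1e-3 m^3 = 1e-3 mol m^-3.
UM_TO_MOL_M3 = 1e-3
MOL_M3_TO_UM = 1e3
#: 1 mol m^-3 = 1e6 nmol L^-1.
MOL_M3_TO_NM = 1e6
NM_TO_MOL_M3 = 1e-6

#: 1 m^3 = 1e6 mL; 1 mol = 1e15 fmol.
FMOL_PER_MOL = 1e15
ML_PER_M3 = 1e6
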