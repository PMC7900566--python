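"""Physical constants used throughout the package.

Average atomic masses are used for peak-position arithmetic because native
electrospray spectra of a ~16 kDa protein do not resolve the isotopic
envelope; the single-isotope masses are used only by the metal-identity
ambiguity check.
"""

#: Mass of a proton, Da (charge carrier in positive-mode electrospray).
PROTON_MASS = 1.00728

#: Average molecular mass of N2 drift gas, Da.  The monoisotopic value
#: (28.006148) differs by <0.03%; the reduced-mass factor it enters is
#: affected by <0.02% for these ions.  Configurable wherever it is used.
N2_MASS = 28.0134

#: Average atomic masses, Da.
CU_AVG = 63.546
ZN_AVG = 65.38

#: Single-isotope masses (AME2003), Da.  Their difference, 0.999545 Da, is
#: what makes Cu-only and Zn-only metalation indistinguishable on a TOF with
#: broad native-protein envelopes.
CU63_MASS = 62.9295975
ZN64_MASS = 63.9291422
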