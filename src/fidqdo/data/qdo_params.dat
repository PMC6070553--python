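# Default free-atom QDO parameter table (editable; indicative values only).
#
# alpha1_free: free-atom dipole polarizability, bohr^3 (Tkatchenko-Scheffler
#              free-atom reference values).
# alpha2_free: free-atom quadrupole polarizability, bohr^5.  These are
#              indicative literature-level magnitudes, NOT authoritative
#              reference data; replace with values appropriate to your own
#              parameterization (hydrogen's 15.0 is the exact atomic value).
# omega:       characteristic QDO frequency, hartree/hbar, derived from the
#              identical-atom London closure omega = 4 C6 / (3 alpha1^2)
#              with TS free-atom C6 coefficients.
#
# element  alpha1_free  alpha2_free   omega
H          4.50         15.0          0.4280
C          12.0         48.8          0.4315
N          7.40         27.9          0.5891
O          5.40         16.0          0.7133
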