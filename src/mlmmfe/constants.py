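"""Physical constants in the package's unit system.

Units throughout: energies kJ/mol, distances Å, charges in elementary
charges (e), forces kJ/mol/Å, temperatures K, times fs (MD) / ps (protocols),
masses amu.
"""

#: Coulomb constant k_e = e^2 / (4 pi eps0), in kJ Å mol^-1 e^-2 (CODATA-derived).
COULOMB_CONSTANT = 1389.35457644

#: Boltzmann constant in kJ mol^-1 K^-1 (CODATA 2018 exact).
BOLTZMANN_CONSTANT = 0.008314462618

#: Conversion for Langevin dynamics: with positions in Å, energies in kJ/mol,
#: masses in amu and time in fs, accelerations need F/m scaled by this factor
#: (1 kJ/mol/Å / amu = 1e-4 Å/fs^2).
ACCEL_UNIT = 1.0e-4
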