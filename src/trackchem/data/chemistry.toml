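# Default chemistry parameter set for liquid-water radiolysis.
# Units as configured: diffusion coefficients in m^2/s, rate constants in
# dm^3/(mol s), energies in eV, times in ps. Converted to internal nm/ps/eV
# units once at load.

[species."H3O+"]
D_m2_per_s = 9.0e-9
charge = 1

[species."H"]
D_m2_per_s = 7.0e-9
charge = 0

[species."OH-"]
D_m2_per_s = 5.0e-9
charge = -1

[species."eaq-"]
D_m2_per_s = 4.9e-9
charge = -1

[species."H2"]
D_m2_per_s = 5.0e-9
charge = 0

[species."OH"]
D_m2_per_s = 2.8e-9
charge = 0

[species."H2O2"]
D_m2_per_s = 1.4e-9
charge = 0

# Bimolecular channels; water is implicit solvent where it appears in the
# stoichiometry (2eaq- + 2H2O, eaq- + H + H2O, products "2H2O" = no tracked
# product).
[[reactions]]
reactants = ["eaq-", "eaq-"]
products = ["H2", "OH-", "OH-"]
k_dm3_per_mol_s = 5.00e9

[[reactions]]
reactants = ["eaq-", "OH"]
products = ["OH-"]
k_dm3_per_mol_s = 2.95e10

[[reactions]]
reactants = ["eaq-", "H"]
products = ["OH-", "H2"]
k_dm3_per_mol_s = 2.65e10

[[reactions]]
reactants = ["eaq-", "H3O+"]
products = ["H"]
k_dm3_per_mol_s = 2.11e10

[[reactions]]
reactants = ["eaq-", "H2O2"]
products = ["OH-", "OH"]
k_dm3_per_mol_s = 1.41e10

[[reactions]]
reactants = ["OH", "OH"]
products = ["H2O2"]
k_dm3_per_mol_s = 4.40e9

[[reactions]]
reactants = ["OH", "H"]
products = []
k_dm3_per_mol_s = 1.44e10

[[reactions]]
reactants = ["H", "H"]
products = ["H2"]
k_dm3_per_mol_s = 1.20e10

[[reactions]]
reactants = ["H3O+", "OH-"]
products = []
k_dm3_per_mol_s = 1.43e11

# Branching of activated water. Fractions are percent and must sum to 100
# within each parent state. Auto-ionization channels list the hydrated
# electron among the products; it additionally receives a thermalization
# displacement when placed.
[[dissociation]]
parent = "ionized"
mode = "dissociative_decay"
products = ["H3O+", "OH"]
fraction_percent = 100.0

[[dissociation]]
parent = "A1B1"
mode = "dissociative_decay"
products = ["OH", "H"]
fraction_percent = 65.0

[[dissociation]]
parent = "A1B1"
mode = "relaxation"
products = []
fraction_percent = 35.0

[[dissociation]]
parent = "B1A1"
mode = "auto_ionization"
products = ["H3O+", "OH", "eaq-"]
fraction_percent = 55.0

[[dissociation]]
parent = "B1A1"
mode = "dissociative_decay"
products = ["OH", "OH", "H2"]
fraction_percent = 15.0

[[dissociation]]
parent = "B1A1"
mode = "relaxation"
products = []
fraction_percent = 30.0

[[dissociation]]
parent = "rydberg_diffuse"
mode = "auto_ionization"
products = ["H3O+", "OH", "eaq-"]
fraction_percent = 50.0

[[dissociation]]
parent = "rydberg_diffuse"
mode = "relaxation"
products = []
fraction_percent = 50.0

[[dissociation]]
parent = "dissoc_attachment"
mode = "dissociative_decay"
products = ["OH", "OH-", "H2"]
fraction_percent = 100.0

[constants]
water_density_g_cm3 = 1.0
sub_excitation_threshold_eV = 8.22
dt_min_ps = 1.0
chem_t_start_ps = 1.0
chem_t_end_ps = 1.0e6

[constants.tracking_cuts_eV]
electron = 7.4
proton = 100.0
hydrogen = 100.0
He0 = 1000.0
"He+" = 1000.0
"He++" = 1000.0
generic_ion_per_u = 0.5e6
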