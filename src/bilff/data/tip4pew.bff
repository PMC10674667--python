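# TIP4P-Ew rigid four-site water model (standard literature constants).
# The negative charge sits on the massless M site on the HOH bisector;
# the oxygen carries the only Lennard-Jones centre.  Geometry is held
# rigid by SHAKE constraints defined on the molecule template, so no
# bonded parameters are needed here.
[types]
species = TIP4PEW
OW MW_O O 15.999 0.0 3.16435 0.680946
HW MW_H H 1.008 0.52422 0.0 0.0
MW MW_M M 0.0 -1.04844 0.0 0.0
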