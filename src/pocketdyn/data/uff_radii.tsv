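# UFF atomic radii (Å): half the van-der-Waals nonbond distance x_I of
# Rappe, Casewit, Colwell, Goddard & Skiff, Universal Force Field (1992).
# These are the radii commonly used by continuum-cavity builders.
# element	radius_A
H	1.4430
He	1.1810
Li	1.2255
Be	1.3725
B	2.0415
C	1.9255
N	1.8300
O	1.7500
F	1.6820
Ne	1.6215
Na	1.4915
Mg	1.5105
Al	2.2495
Si	2.1475
P	2.0735
S	2.0175
Cl	1.9735
Ar	1.9340
K	1.9060
Ca	1.6995
Fe	1.4560
Cu	1.7480
Zn	1.2455
Br	2.0945
I	2.2300
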