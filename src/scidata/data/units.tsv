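symbol	quantity_kind	dimensions	multiplier_to_si	offset_to_si
m	length	m:1	1	0
g	mass	kg:1	0.001	0
s	time	s:1	1	0
A	electric current	A:1	1	0
K	temperature	K:1	1	0
mol	amount of substance	mol:1	1	0
cd	luminous intensity	cd:1	1	0
Hz	frequency	s:-1	1	0
N	force	kg:1 m:1 s:-2	1	0
Pa	pressure	kg:1 m:-1 s:-2	1	0
J	energy	kg:1 m:2 s:-2	1	0
W	power	kg:1 m:2 s:-3	1	0
C	electric charge	A:1 s:1	1	0
V	electric potential	kg:1 m:2 s:-3 A:-1	1	0
F	capacitance	A:2 kg:-1 m:-2 s:4	1	0
ohm	electric resistance	kg:1 m:2 s:-3 A:-2	1	0
S	electric conductance	A:2 kg:-1 m:-2 s:3	1	0
T	magnetic flux density	kg:1 s:-2 A:-1	1	0
Wb	magnetic flux	kg:1 m:2 s:-2 A:-1	1	0
L	volume	m:3	0.001	0
min	time	s:1	60	0
h	time	s:1	3600	0
day	time	s:1	86400	0
degC	temperature	K:1	1	273.15
atm	pressure	kg:1 m:-1 s:-2	101325	0
bar	pressure	kg:1 m:-1 s:-2	100000	0
mmHg	pressure	kg:1 m:-1 s:-2	133.322387415	0
Torr	pressure	kg:1 m:-1 s:-2	133.3223684210526	0
cal	energy	kg:1 m:2 s:-2	4.184	0
eV	energy	kg:1 m:2 s:-2	1.602176634E-19	0
Da	mass	kg:1	1.66053906660E-27	0
angstrom	length	m:1	1E-10	0
M	amount concentration	mol:1 m:-3	1000	0
1/cm	wavenumber	m:-1	100	0
ppm	dimensionless ratio		1E-6	0
ppb	dimensionless ratio		1E-9	0
%	dimensionless ratio		0.01	0
rad	plane angle		1	0
deg	plane angle		1.7453292519943295E-2	0
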