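code,name,area,TL,B,PB,QB,EE,PQ,OI,VIC,VRB
SL,Atlantic thread herring,Original,2.69,1.18e-02,0.580,1.619,0.868,3.58e-01,0.249,3.74e-03,
BL,Skipjack tuna,Original,4.67,4.52e-05,0.340,0.749,0.772,4.53e-01,0.324,3.19e-05,
DO,Dolphinfish,Original,4.72,2.52e-05,0.180,1.212,0.772,1.48e-01,0.480,2.50e-05,
ES,Largehead hairtail,Original,4.71,1.04e-04,0.360,0.661,0.772,5.44e-01,0.177,8.27e-06,
GU,Castin leatherjacket,Original,3.54,1.32e-04,0.480,0.661,0.868,7.26e-01,0.079,4.61e-05,
OL,Yellowtail amberjack,Original,4.07,1.92e-06,0.180,1.212,0.772,1.48e-01,0.001,0,
XI,Rough scad,Original,3.06,8.93e-05,0.430,1.092,0.868,3.93e-01,0.011,3.74e-04,
OC,Atlantic bigeye,Original,2.99,4.62e-05,0.570,5.300,0.648,1.07e-01,1.000,0,
PEP,Pelagic fish,Original,2.95,1.93e-07,2.500,25.000,0.742,1.00e-01,0.100,0,
TA,Lebranche mullet,Original,2.00,3.64e-03,0.320,1.296,0.648,2.46e-01,0,5.90e-04,
GA,Atlantic moonfish,Original,3.55,7.93e-04,0.750,0.987,0.868,7.59e-01,0.067,1.36e-04,
XA,Crevalle jack,Original,3.58,1.62e-07,0.570,5.300,0.868,1.07e-01,0.0,3.20e-04,
PA,Atlantic bumper,Original,3.13,5.66e-03,0.400,0.943,0.868,4.24e-01,0.462,8.65e-04,
CA,Atlantic chub mackerel,Original,3.38,6.73e-03,0.480,0.950,0.868,5.05e-01,0.492,4.51e-04,
CEF,Cephalopods,Original,3.82,8.10e-11,3.000,10.000,0.858,3.00e-01,0.282,0,
LUL,Squids,Original,3.39,1.16e-07,0.680,5.155,0.858,1.31e-01,0.476,1.16e-07,
PAB,Benthic feeding fish,Original,3.25,1.28e-07,0.960,7.600,0.648,1.26e-01,0.144,0,
SC,False herring,Original,2.77,2.09e-04,0.930,1.500,0.868,6.20e-01,0.288,0,
CO,Whitemouth croaker,Original,3.48,1.82e-03,0.340,0.801,0.800,4.24e-01,0.149,6.41e-04,
SV,Brazilian sardine,Original,2.74,2.53e-04,0.810,1.714,0.868,4.72e-01,0.231,2.57e-04,
OBD,Detritivorous benthic organisms,Original,2.14,7.53e-07,7.860,13.450,0.501,5.84e-01,0.130,0,
OBC,Carnivorous benthic organisms,Original,2.53,1.99e-07,6.630,12.220,0.711,5.42e-01,0.354,0,
PAP,Pelagic feeding fish,Original,3.91,2.90e-11,1.300,2.800,0.868,4.64e-01,0.018,0,
CAR,Crabs,Original,3.01,9.40e-11,4.420,25.800,0.729,1.71e-01,0.905,0,
EQU,Echinoderms,Original,2.26,2.70e-06,1.580,2.860,0.137,5.52e-01,0.214,0,
INB,Benthic invertebrates,Original,3.37,8.38e-07,2.680,3.894,0.950,6.88e-01,0.044,0,
CAM,Shrimps,Original,2.58,5.50e-11,3.930,19.130,0.622,2.05e-01,0.297,0,
MOL,Mollusks,Original,2.32,3.12e-07,5.290,8.210,0.950,6.44e-01,0.233,0,
ZOO,Zooplankton,Original,2.05,8.00e+00,40.000,324.600,0.429,1.23e-01,0.053,0,
CNI,Cnidaria,Original,2.61,2.40e-11,1.000,2.000,0.551,5.00e-01,0.311,0,
POL,Polychaeta,Original,2.00,1.07e-05,6.320,11.190,0.205,5.64e-01,0,0,
BAP,Bacterioplankton,Original,2.00,3.70e-11,250.000,500.000,0.689,5.00e-01,0,0,
ALG,Algae,Original,1.00,1.44e-09,41.660,,0.950,,0,0,
FIT,Fitoplankton,Original,1.00,1.67e+01,100000.000,,0.965,,0,0,
DET,Detritus,Original,1.00,1.50e+02,,,0.000,,0.013,0,
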