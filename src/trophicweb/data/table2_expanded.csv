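code,name,area,TL,B,PB,QB,EE,PQ,OI,VIC,VRB
SL,Atlantic thread herring,Expanded,2.69,4.16e-03,0.580,1.619,0.868,3.58e-01,0.249,4.09e-03,6.88e-04
BL,Skipjack tuna,Expanded,4.67,1.18e-04,0.340,0.749,0.772,4.53e-01,0.324,1.02e-04,5.49e-06
DO,Dolphinfish,Expanded,4.72,4.44e-05,0.180,1.212,0.772,1.48e-01,0.480,2.92e-05,1.69e-06
ES,Largehead hairtail,Expanded,4.71,1.59e-05,0.360,0.661,0.772,5.44e-01,0.177,8.69e-06,1.25e-05
GU,Castin leatherjacket,Expanded,3.54,5.50e-05,0.480,0.661,0.868,7.26e-01,0.079,6.29e-06,1.08e-04
OL,Yellowtail amberjack,Expanded,4.07,2.56e-06,0.180,1.212,0.772,1.48e-01,0.001,2.56e-06,0
XI,Rough scad,Expanded,3.06,5.04e-04,0.430,1.092,0.868,3.93e-01,0.011,3.74e-04,8.93e-05
OC,Atlantic bigeye,Expanded,2.99,4.62e-05,0.570,5.300,0.648,1.07e-01,1.000,4.60e-05,0
PEP,Pelagic fish,Expanded,2.95,1.93e-07,2.500,25.000,0.742,1.00e-01,0.100,0,0
TA,Lebranche mullet,Expanded,2.00,2.40e-04,0.320,1.296,0.648,2.46e-01,0,1.42e-04,3.50e-05
GA,Atlantic moonfish,Expanded,3.55,3.89e-04,0.750,0.987,0.868,7.59e-01,0.067,3.72e-04,2.21e-04
XA,Crevalle jack,Expanded,3.58,6.13e-04,0.570,5.300,0.868,1.07e-01,0,0,0
PA,Atlantic bumper,Expanded,3.13,1.26e-03,0.400,0.943,0.868,4.24e-01,0.462,1.35e-03,1.55e-04
CA,Atlantic chub mackerel,Expanded,3.38,1.53e-03,0.480,0.950,0.868,5.05e-01,0.492,7.66e-04,9.00e-04
CEF,Cephalopods,Expanded,3.82,8.10e-11,3.000,10.000,0.858,3.00e-01,0.282,0,0
LUL,Squids,Expanded,3.39,3.29e-07,0.680,5.155,0.858,1.31e-01,0.476,3.29e-07,0
PAB,Benthic feeding fish,Expanded,3.25,1.28e-07,0.960,7.600,0.648,1.26e-01,0.144,0,0
SC,False herring,Expanded,2.77,2.09e-04,0.930,1.500,0.868,6.20e-01,0.288,2.09e-04,0
CO,Whitemouth croaker,Expanded,3.48,2.19e-05,0.340,0.801,0.800,4.24e-01,0.149,9.35e-06,1.00e-05
SV,Brazilian sardine,Expanded,2.74,1.37e-02,0.810,1.714,0.868,4.72e-01,0.231,1.24e-02,5.02e-03
OBD,Detritivorous benthic organisms,Expanded,2.14,7.53e-07,7.860,13.450,0.501,5.84e-01,0.130,0,0
OBC,Carnivorous benthic organisms,Expanded,2.53,1.99e-07,6.630,12.220,0.711,5.42e-01,0.354,0,0
PAP,Pelagic feeding fish,Expanded,3.91,2.90e-11,1.300,2.800,0.868,4.64e-01,0.018,0,0
CAR,Crabs,Expanded,3.01,9.40e-11,4.420,25.800,0.729,1.71e-01,0.905,0,0
EQU,Echinoderms,Expanded,2.26,2.70e-06,1.580,2.860,0.137,5.52e-01,0.214,0,0
INB,Benthic invertebrates,Expanded,3.37,8.38e-07,2.680,3.894,0.950,6.88e-01,0.044,0,0
CAM,Shrimps,Expanded,2.58,5.50e-11,3.930,19.130,0.622,2.05e-01,0.297,0,0
MOL,Mollusks,Expanded,2.32,3.12e-07,5.290,8.210,0.950,6.44e-01,0.233,0,0
ZOO,Zooplankton,Expanded,2.05,8.00e+00,40.000,324.600,0.429,1.23e-01,0.053,0,0
CNI,Cnidaria,Expanded,2.61,2.40e-11,1.000,2.000,0.551,5.00e-01,0.311,0,0
POL,Polychaeta,Expanded,2.00,1.07e-05,6.320,11.190,0.205,5.64e-01,0,0,0
BAP,Bacterioplankton,Expanded,2.00,3.70e-11,250.000,500.000,0.689,5.00e-01,0,0,0
ALG,Algae,Expanded,1.00,1.44e-09,41.660,,0.950,,0,0,0
FIT,Fitoplankton,Expanded,1.00,1.67e+01,100000.000,,0.965,,0,0,0
DET,Detritus,Expanded,1.00,1.50e+02,67.500,,,5.24e-08,0.013,0,0
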