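----- Begin chunk -----
Image filename: run0007_shot_000012.h5
Acquisition number: 12
wavelength_A_1 = 1.771300
wavelength_A_2 = 1.377900
beam_divergence_mrad = 0.05
Peaks from peak search
  fast/px slow/px intensity/ADU snr
  120.500 340.250 15230.000 42.100
  402.125 77.875 8110.500 18.300
  255.000 255.000 950.250 6.100
End of peak list
--- Begin crystal
Cell parameters 78.2100 78.2100 39.0500 A, 90.0000 90.0000 90.0000 deg
colour = 9keV
wavelength_A = 1.377900
Reflections measured after indexing
  h k l intensity/ADU sigma/ADU fast/px slow/px
  3 1 2 1520.000 40.000 120.400 340.300
  -2 4 1 310.500 22.000 402.000 78.000
End of reflections
--- End crystal
----- End chunk -----
----- Begin chunk -----
Image filename: run0007_shot_000013.h5
Acquisition number: 13
wavelength_A_1 = 1.770800
wavelength_A_2 = 1.378400
Peaks from peak search
  fast/px slow/px intensity/ADU snr
  88.000 91.500 2300.000 11.000
End of peak list
----- End chunk -----
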