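# Czerny-Turner spectrograph, 500 mm parabolic mirrors, 300 lines/mm
# plane-ruled reflection grating, 1024 x 26 um CCD row.
# half_deviation_deg carries the sign of the counterclockwise-positive
# angle convention under which the detector captures the n = -1 order;
# the measured magnitude is 21.88 deg.  grating_angle_deg selects a neon
# band of roughly 631-740 nm.
focal_length_mm = 500.0
pixel_pitch_um = 26.0
grating_lines_per_mm = 300.0
half_deviation_deg = -21.88
grating_angle_deg = -74.0
grating_type = reflection
diffraction_order = -1
n_pixels = 1024
center_offset_um = 0.0
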