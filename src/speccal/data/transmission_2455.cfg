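# Lens-based transmission spectrometer: 85 mm lenses, fixed 2455 lines/mm
# volume-phase holographic grating at 45 deg to the optical axis,
# 1024 x 26 um CCD row.  The detector sits on the first-order arm
# (deviation ~90 deg), so the incident and diffracted sine terms of the
# grating equation add: model_sign = -1 overrides the straight-through
# transmission sign.  Modeled band ~528-617 nm.
focal_length_mm = 85.0
pixel_pitch_um = 26.0
grating_lines_per_mm = 2455.0
half_deviation_deg = 45.0
grating_angle_deg = 0.0
grating_type = transmission
diffraction_order = 1
n_pixels = 1024
center_offset_um = 0.0
model_sign = -1
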