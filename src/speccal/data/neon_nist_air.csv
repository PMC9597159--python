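# Strong Ne I emission lines, air wavelengths (nm), from the NIST Atomic
# Spectra Database.  Uncertainties are indicative (nm).
wavelength_nm,uncertainty_nm,label
540.056,0.001,Ne I
576.442,0.001,Ne I
585.249,0.001,Ne I
588.190,0.001,Ne I
594.483,0.001,Ne I
597.553,0.001,Ne I
602.999,0.001,Ne I
607.434,0.001,Ne I
609.616,0.001,Ne I
614.306,0.001,Ne I
616.359,0.001,Ne I
621.728,0.001,Ne I
626.650,0.001,Ne I
630.479,0.001,Ne I
633.443,0.001,Ne I
638.299,0.001,Ne I
640.225,0.001,Ne I
650.653,0.001,Ne I
653.288,0.001,Ne I
659.895,0.001,Ne I
667.828,0.001,Ne I
671.704,0.001,Ne I
692.947,0.001,Ne I
702.405,0.001,Ne I
703.241,0.001,Ne I
705.911,0.001,Ne I
717.394,0.001,Ne I
724.517,0.001,Ne I
743.890,0.001,Ne I
748.887,0.001,Ne I
753.577,0.001,Ne I
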