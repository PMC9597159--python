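# SYNTHETIC krypton-like line list for demonstration and simulation only:
# twelve lines spread over the 556-606 nm band of the transmission
# spectrometer (the 528-556 nm region is deliberately empty, as for the
# real lamp).  These are NOT certified reference wavelengths.
wavelength_nm,uncertainty_nm,label
556.222,0.002,Kr-like
557.029,0.002,Kr-like
560.155,0.002,Kr-like
565.111,0.002,Kr-like
567.248,0.002,Kr-like
574.683,0.002,Kr-like
583.282,0.002,Kr-like
587.092,0.002,Kr-like
592.841,0.002,Kr-like
599.386,0.002,Kr-like
603.271,0.002,Kr-like
605.613,0.002,Kr-like
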