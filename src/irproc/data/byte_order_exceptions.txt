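# Camera models whose embedded raw payload inverts the usual byte-order rule
# (PNG payload -> little-endian samples, TIFF payload -> big-endian samples).
# One model name per line, exactly as reported in the "Camera Model" tag.
# A handful of models in the field are known to need this inversion; add the
# model string here if raw images from your camera decode to obviously wrong
# digital numbers (e.g. temperatures of thousands of degrees).
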