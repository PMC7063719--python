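{
 "dose_rate_constant_cGy_per_h_U": 1.12,
 "active_length_mm": 3.5,
 "note": "Generic Ir-192 HDR point-source fixture: g(r) from the classic Meisberger polynomial, Lambda a point-source consensus-style value, anisotropy table synthetic."
}
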