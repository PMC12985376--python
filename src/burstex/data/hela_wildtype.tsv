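protein	copy_number	bound_fraction	residence_time_s
RAD21	264000	0.65	822
NIPBL	111000	0.40	72
PDS5	164000	0.45	70
WAPL	65000	0.35	45
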