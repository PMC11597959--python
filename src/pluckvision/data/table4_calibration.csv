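species,slope,intercept_regression,intercept_upper,coverage
pansy,0.36,26.33,43.20,0.85
snapdragon,0.38,5.33,34.57,0.85
marigold,0.66,7.10,37.91,0.85
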