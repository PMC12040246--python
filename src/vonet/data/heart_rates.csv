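species,hr_mean_bpm,hr_sd_bpm,source
rat,363,14,literature-average
dog,95,4,literature-average
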