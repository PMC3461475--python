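# Registry pathway proportions as printed (rounded): of 2,717 consecutive
# stress-CMR patients with suspected CAD, 21% positive, 6% uncertain,
# 73% negative; uncertain patients had SEcho 85%, cardiac CT 13%, SPECT 2%.
# The calibration module recovers the unrounded fractions; this preset is
# the rounded alternative.
p_positive: 0.21
p_uncertain: 0.06
p_negative: 0.73
uncertain_split: {SECHO: 0.85, CT: 0.13, SPECT: 0.02}
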