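# Healthy-reference calibration (mean, sd) for Total Score z-thresholding.
# Frozen from a 50-subject healthy synthetic calibration cohort (rest and
# stress phases pooled, default generator settings).  Units match the
# extraction pipeline exports.  Substitute a device-specific calibration
# for real recordings.
cmd: [25.79, 3.71]
pdd: [126.4, 22.7]
cad: [39.7, 11.1]
tdisp: [10.95, 0.26]
vmcg: [0.048, 0.0074]
plp_slope: [0.13, 0.19]
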