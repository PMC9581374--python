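epss,lvdd,wall_motion,survival
medium,medium,low,2
medium,medium,high,3
medium,medium,low,4
high,low,high,22
low,high,low,30
high,low,low,35
low,medium,high,40
medium,high,low,41
high,low,high,50
low,high,low,55
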