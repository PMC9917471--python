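sample_id	group
green_1	green
green_2	green
green_3	green
red_1	red
red_2	red
red_3	red
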