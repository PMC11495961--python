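element_type,intensity_class
body_ripple,high
mock_attack,high
body_shudder,low
decoration_toss,low
wing_flick,low
wing_droop,low
head_bob,low
head_tilt,low
bowing,low
crouch_display,low
hop,low
run_around,low
pivot,low
tail_flick,low
neck_stretch,low
bill_wipe,low
vocal_display,low
freeze,low
strut,low
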