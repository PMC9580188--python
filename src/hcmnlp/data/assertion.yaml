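# Assertion-scope configuration (NegEx-style defaults).
# pre_window:  max tokens between a preceding cue and the target
# post_window: max tokens between the target and a following cue
pre_window: 6
post_window: 4
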