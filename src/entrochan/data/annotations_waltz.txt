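0:20–1:16	Pleasure
1:17–2:21	Excitement
2:22–3:01	Pleasure
3:02–3:24	Excitement
3:25–3:41	Pleasure
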