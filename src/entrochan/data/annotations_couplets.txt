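0:06–0:33	Excitement
0:34–0:42	Briskness
0:43–0:52	Nervousness
0:53–1:07	Excitement
1:08–1:57	Briskness
1:58–2:25	Excitement
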