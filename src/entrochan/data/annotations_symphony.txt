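0:16–0:45	Passion
0:46–1:05	Relaxation
1:06–1:23	Cheerfulness
1:24–1:41	Passion
1:42–1:53	Relaxation
1:54–2:10	Nervousness
2:11–2:37	Relaxation
2:38–2:55	Cheerfulness
2:56–4:15	Nervousness
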