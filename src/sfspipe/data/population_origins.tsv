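population	group	lat	lon	origin_city
LWK	Africa	0.62	34.77	Webuye
YRI	Africa	7.38	3.90	Ibadan
CEU	Europe	48.85	2.35	Paris
TSI	Europe	43.77	11.25	Florence
CHB	EastAsia	39.91	116.40	Beijing
CHD	EastAsia	39.91	116.40	Beijing
JPT	EastAsia	35.68	139.69	Tokyo
GIH	India	23.03	72.58	Ahmedabad
Brahmin	India	17.39	78.49	Hyderabad
Yadava	India	17.39	78.49	Hyderabad
Mala/Madiga	India	17.39	78.49	Hyderabad
Irula	India	17.39	78.49	Hyderabad
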