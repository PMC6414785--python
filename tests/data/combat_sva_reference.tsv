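s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	 9.27405216178	10.27772229592	 9.65376205119	 8.39890136715	 9.56035832549	 8.74810529946	10.39388327360	 9.56229683647	 9.44142846184	 8.99707978720
g1	 9.07028292368	 7.70966292090	 7.43913544138	 7.51441947803	 8.38829644924	 7.82277484348	 7.86385831947	 7.87957320262	 9.36590990708	 7.15219695802
g2	 8.27982572611	 7.99353121932	 9.35104187487	 9.83811460776	 8.65799621859	 7.88846721406	 7.90243603712	 9.21693073084	 9.29950482304	 9.12118816913
g3	 7.86855603272	 8.65450104497	 8.55339785556	 8.64270516239	 9.21420393240	 8.36456614000	 8.79955700367	 8.21551483752	 8.42716475277	 8.75405784501
g4	 5.27684556328	 6.49172375548	 6.33076870614	 6.15079854675	 6.53928243759	 7.50852158576	 5.54738282508	 7.07101260510	 4.86865320302	 5.98844988290
g5	10.07573002721	10.51074361013	10.63915563510	10.72351500516	 9.55030833821	10.26363674489	11.38378624008	10.49359002862	 9.57361389530	 9.69442351975
g6	 9.15409388628	10.45654539392	10.13039764844	10.63429042692	 9.60662831109	10.23594141938	10.66181460630	 9.80930636886	10.50788303481	 9.48781212345
g7	10.43817099077	10.42189995304	 9.71293791671	11.17841801123	10.34555720574	10.42130994793	10.85953120907	10.82751012906	11.03232791064	10.31744799840
g8	 6.69389154013	 7.03496385129	 5.43908161354	 5.67755019580	 5.80105496683	 5.44343694528	 6.65276881317	 5.52287575622	 5.97934750913	 7.43138161108
g9	 7.10491788485	 8.19745033436	 6.52822245486	 7.25557233093	 6.51183678367	 6.83972455337	 7.85655915410	 5.64273542547	 7.50660326972	 7.33701773875
g10	 6.17215468091	 5.32259939311	 6.83659416100	 6.23663337145	 6.99669750225	 6.09337181186	 7.45482941162	 5.86828333316	 5.19257105445	 6.22902709248
g11	 9.31070527483	10.34162254474	 9.86735669273	 9.43457051837	10.43584229151	 9.48488967511	 9.99168179582	 9.72691440093	10.22240281754	 9.31141800975
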