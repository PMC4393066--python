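# halting model: D_JS thresholds t(L, p), bits
quantile	0.95
min_len	3000
replicates	1500
seed	94110
gcs	0.3	0.4	0.5	0.6
6000	0.00045298924096066857	0.00045898619391949666	0.00047525998029577024	0.0004689607519149449
12000	0.00045298924096066857	0.0004347627344691327	0.00047525998029577024	0.00046257827274368577
25000	0.00025802034125833477	0.0002586024546926163	0.0002547017112285282	0.0002689604439622024
50000	0.0001376841315514108	0.000136837525150578	0.00013724620592573037	0.00014161316111365886
100000	7.648974249595989e-05	7.303798276654635e-05	7.454544700455144e-05	7.388254708930217e-05
200000	3.8222005037495006e-05	3.755086325072547e-05	3.805193080509703e-05	3.789115978541439e-05
400000	1.9297563965285406e-05	2.033208896361961e-05	1.9680320805113886e-05	2.077089869771272e-05
800000	1.0059886703403968e-05	1.002441926079873e-05	9.856636211659073e-06	1.0120853795997587e-05
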