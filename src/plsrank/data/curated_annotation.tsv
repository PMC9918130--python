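gene_id	is_neurogenesis	is_tf	behavior_terms
Nr1d1	1	1	abnormal anxiety-related response
Fmr1	1	1	abnormal aggression-related behavior|increased aggression|abnormal anxiety-related response|abnormal fear-related response|abnormal response to social novelty|abnormal learning/memory/conditioning
Atf2	1	1	abnormal anxiety-related response
Braf	1	0	abnormal aggression-related behavior|increased aggression
Pten	1	0	abnormal aggression-related behavior|abnormal anxiety-related response|abnormal fear-related response
Fxr2	1	1	abnormal fear-related response
Creb1	1	1
Egr1	1	1
Htr2c	1	0
Prlr	1	0
Epha5	1	0
Notch3	1	0
Slc7a11	1	0
Mif	1	0
Spred1	0	0	abnormal anxiety-related response
Elavl2	0	1
Nufip2	0	0
Sacm1l	0	0
Xpo1	0	0
Pcmtd2	0	0
Hnrnpc	0	0
9330159F19Rik	0	0
Tmem33	0	0
Pcnp	0	0
Picalm	0	0
Rexo1	0	0
Tmem229a	0	0
Lztfl1	0	0
Pcm1	0	0
Abcb7	0	0
Azin1	0	0
Rlim	0	0
Far1	0	0
Dzip3	0	0
Eif5a2	0	0
Pum2	0	0
Lnp	0	0
Vcpip1	0	0
Taok1	0	0
Fndc3a	0	0
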