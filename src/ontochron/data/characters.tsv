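index	name
1	Fecundation
2	Perivitelline space
3	Bipolar differentiation
4	Blastodisc
5	Cleavage
6	Two blastomeres
7	Four blastomeres
8	Morula
9	Blastula
10	Gastrula
11	Neurulation
12	Somites (around 10)
13	Rudimentary heart
14	Rudimentary eyes
15	Brain begins
16	Tail bud
17	Eye lenses
18	Vibrations of muscle
19	Full number of somites
20	Pulsating heart
21	Development of embryonic finfold
22	Segmentation of the caudal part completed
23	Hatching glands
24	First hatching
25	Rudiment of the pectoral fins
26	Otoliths appear
27	Development of vena caudalis inferior
28	Separation of front of head from the yolk sac
29	Development of the ducti Cuvieri on yolk sac
30	Last hatching
31	Complete separation of head from yolk sac
32	Pigment of the eye
33	Development of semicircular canals
34	First pigmentation on body
35	Lower jaw starts moving
36	Development of gill lamellae
37	First movements of pectoral fins
38	Mouth opening
39	Development of lepidotrichia in the caudal fin
40	Branchial respiration started
41	Gas bladder filled with gas
42	Finfold begins to differentiate into zones of individual unpaired fins
43	Start exogenous feeding
44	Respiration function fully taken by gills
45	Yolk has completely disappeared
46	Development of lepidotrichia in dorsal fin
47	Change to exclusively exogenous feeding
48	Development of lepidotrichia in pectoral fins
49	Development of lepidotrichia in anal fin
50	Complete number of rays in anal fin
51	Complete number of rays in dorsal fin
52	Lepidotrichia developed in the pelvic fin
53	Full number of rays in all fins
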