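rank	mirna_id	family_id	logFC	ave_exp	p_value	adj_p_val
1	mmu-let-7g-5p	let-7	0.30	12.20	2.12E-07	1.27E-04
2	mmu-let-7d-5p	let-7	0.27	11.53	5.98E-07	1.27E-04
4	mmu-let-7c-5p	let-7	0.29	11.78	1.09E-06	1.49E-04
5	mmu-let-7b-5p	let-7	0.25	12.48	1.17E-06	1.49E-04
10	mmu-let-7a-5p	let-7	0.27	12.59	9.73E-06	6.88E-04
7	mmu-let-7i-5p	let-7	0.24	11.17	1.08E-05	6.88E-04
22	mmu-let-7e-5p	let-7	0.21	11.25	1.67E-04	4.83E-03
42	mmu-miR-125a-5p	mir-10	0.22	11.79	1.49E-03	2.26E-02
12	mmu-miR-101b-3p	mir-101	0.29	7.79	1.72E-05	9.11E-04
37	mmu-miR-101a-3p	mir-101	0.24	10.12	1.17E-03	1.92E-02
50	mmu-miR-107-3p	mir-103	0.22	8.77	3.24E-03	4.12E-02
64	mmu-miR-124-5p	mir-124	0.15	6.32	7.13E-03	7.09E-02
33	mmu-miR-301a-3p	mir-130	0.22	8.39	6.90E-04	1.29E-02
59	mmu-miR-130a-3p	mir-130	0.16	8.30	5.94E-03	6.44E-02
52	mmu-miR-135b-5p	mir-135	0.22	7.92	4.08E-03	4.99E-02
74	mmu-miR-136-5p	mir-136	0.22	9.06	1.09E-02	9.39E-02
18	mmu-miR-138-5p	mir-138	0.26	12.84	9.05E-05	3.20E-03
40	mmu-miR-140-3p	mir-140	0.19	7.89	1.23E-03	1.94E-02
46	mmu-miR-144-3p	mir-144	0.25	6.88	2.38E-03	3.30E-02
68	mmu-miR-145-5p	mir-145	0.17	7.03	8.25E-03	7.73E-02
48	mmu-miR-146b-5p	mir-146	0.16	7.50	2.60E-03	3.38E-02
25	mmu-miR-152-3p	mir-148	0.19	6.47	2.22E-04	5.65E-03
31	mmu-miR-149-5p	mir-149	0.22	7.69	4.26E-04	8.75E-03
14	mmu-miR-16-5p	mir-15	0.29	10.94	2.74E-05	1.25E-03
16	mmu-miR-15a-5p	mir-15	0.20	9.18	5.63E-05	2.24E-03
20	mmu-miR-195-5p	mir-15	0.24	8.63	1.26E-04	4.01E-03
53	mmu-miR-15b-5p	mir-15	0.15	6.85	4.15E-03	4.99E-02
44	mmu-miR-93-5p	mir-17	0.16	6.98	1.73E-03	2.45E-02
21	mmu-miR-181d-5p	mir-181	0.24	8.47	1.51E-04	4.59E-03
57	mmu-miR-181a-5p	mir-181	0.20	9.81	5.96E-03	6.44E-02
69	mmu-miR-182-5p	mir-182	0.62	8.71	8.90E-03	8.21E-02
62	mmu-miR-183-5p	mir-183	0.66	8.38	6.90E-03	6.99E-02
49	mmu-miR-185-5p	mir-185	0.19	8.91	2.60E-03	3.38E-02
41	mmu-miR-191-5p	mir-191	0.19	9.71	1.25E-03	1.94E-02
28	mmu-miR-193-3p	mir-193	0.25	6.55	3.70E-04	8.12E-03
29	mmu-miR-1952	mir-1952	0.21	9.18	3.70E-04	8.12E-03
72	mmu-miR-1961	mir-1961	0.19	6.58	1.03E-02	9.11E-02
34	mmu-miR-204-5p	mir-204	0.31	7.74	6.87E-04	1.29E-02
26	mmu-miR-222-3p	mir-221	0.23	10.22	2.37E-04	5.81E-03
35	mmu-miR-221-3p	mir-221	0.25	9.09	8.47E-04	1.54E-02
63	mmu-miR-221-5p	mir-221	0.17	5.61	6.79E-03	6.99E-02
38	mmu-miR-23a-3p	mir-23	0.22	10.57	1.12E-03	1.92E-02
51	mmu-miR-23b-3p	mir-23	0.27	11.85	3.70E-03	4.63E-02
13	mmu-miR-24-2-5p	mir-24	0.24	7.13	1.89E-05	9.26E-04
24	mmu-miR-24-3p	mir-24	0.25	11.70	1.98E-04	5.27E-03
58	mmu-miR-24-1-5p	mir-24	0.17	7.72	5.92E-03	6.44E-02
3	mmu-miR-26a-5p	mir-26	0.30	12.79	4.71E-07	1.27E-04
47	mmu-miR-26b-5p	mir-26	0.29	9.79	2.47E-03	3.35E-02
15	mmu-miR-29a-5p	mir-29	0.29	7.56	3.17E-05	1.34E-03
6	mmu-miR-30d-5p	mir-30	0.26	9.68	3.57E-06	3.79E-04
39	mmu-miR-30e-5p	mir-30	0.26	10.87	1.18E-03	1.92E-02
43	mmu-miR-30e-3p	mir-30	0.29	8.17	1.61E-03	2.38E-02
76	mmu-miR-30b-5p	mir-30	0.25	11.79	1.12E-02	9.39E-02
9	mmu-miR-320-3p	mir-320	0.26	7.49	1.07E-05	6.88E-04
71	mmu-miR-330-5p	mir-330	0.15	7.70	9.69E-03	8.70E-02
30	mmu-miR-335-5p	mir-335	0.23	10.51	4.00E-04	8.50E-03
67	mmu-miR-339-5p	mir-339	0.20	6.80	7.92E-03	7.53E-02
8	mmu-miR-34c-5p	mir-34	0.24	6.68	9.54E-06	6.88E-04
77	mmu-miR-34a-5p	mir-34	0.17	9.54	1.17E-02	9.66E-02
45	mmu-miR-340-5p	mir-340	0.17	8.51	1.71E-03	2.45E-02
17	mmu-miR-361-5p	mir-361	0.24	7.88	7.74E-05	2.90E-03
19	mmu-miR-376b-3p	mir-368	0.26	8.45	1.05E-04	3.50E-03
56	mmu-miR-376a-3p	mir-368	0.19	10.21	5.63E-03	6.40E-02
23	mmu-miR-434-3p	mir-434	0.22	10.46	1.76E-04	4.88E-03
27	mmu-miR-451	mir-451	0.33	10.72	2.79E-04	6.57E-03
66	mmu-miR-669c-5p	mir-467	0.17	8.84	7.68E-03	7.41E-02
55	mmu-miR-485-3p	mir-485	0.19	6.75	5.52E-03	6.39E-02
65	mmu-miR-669n	mir-669n	0.14	7.88	7.46E-03	7.31E-02
60	mmu-miR-674-5p	mir-674	0.17	8.64	6.08E-03	6.45E-02
54	mmu-miR-676-3p	mir-676	0.15	6.63	4.48E-03	5.28E-02
11	mmu-miR-7a-5p	mir-7	0.24	9.17	1.37E-05	7.91E-04
36	mmu-miR-708-5p	mir-708	0.17	9.38	9.09E-04	1.61E-02
70	mmu-miR-429-3p	mir-8	0.61	9.27	9.53E-03	8.68E-02
32	mmu-miR-9-3p	mir-9	0.22	12.96	6.43E-04	1.28E-02
61	mmu-miR-9-5p	mir-9	0.24	12.11	6.91E-03	6.99E-02
73	mmu-miR-96-5p	mir-96	0.53	8.58	1.06E-02	9.22E-02
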