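gene_id	family	domain_count	category
PpSPI1	serpin	1	serpin
PpSPI2	serpin	1	serpin
PpSPI3	serpin	2	serpin
PpSPI4	serpin	1	serpin
PpSPI5	serpin	1	serpin
PpSPI6	serpin	1	serpin
PpSPI7	serpin	1	serpin
PpSPI8	serpin	1	serpin
PpSPI9	serpin	1	serpin
PpSPI10	serpin	1	serpin
PpSPI11	Kazal	1	canonical
PpSPI12	Kazal	1	canonical
PpSPI13	Kazal	3	canonical
PpSPI14	Kazal	1	canonical
PpSPI15	Kazal	1	canonical
PpSPI16	Kazal	1	canonical
PpSPI17	Kazal	1	canonical
PpSPI18	Kazal	1	canonical
PpSPI19	Kazal	1	canonical
PpSPI20	Kazal	1	canonical
PpSPI21	Kazal	1	canonical
PpSPI22	Kazal	1	canonical
PpSPI23	Kazal	1	canonical
PpSPI24	Kazal	1	canonical
PpSPI25	Kazal	1	canonical
PpSPI26	Kazal	1	canonical
PpSPI27	Kazal	11	canonical
PpSPI28	Kazal	3	canonical
PpSPI29	Kazal	1	canonical
PpSPI30	Kazal	1	canonical
PpSPI31	Kazal	8	canonical
PpSPI32	Kazal	1	canonical
PpSPI33	Pacifastin	1	canonical
PpSPI34	Pacifastin	1	canonical
PpSPI35	Pacifastin	7	canonical
PpSPI36	Pacifastin	8	canonical
PpSPI37	Pacifastin	5	canonical
PpSPI38	Pacifastin	9	canonical
PpSPI39	Pacifastin	4	canonical
PpSPI40	Pacifastin	2	canonical
PpSPI41	Pacifastin	1	canonical
PpSPI42	Pacifastin	1	canonical
PpSPI43	Pacifastin	2	canonical
PpSPI44	Pacifastin	1	canonical
PpSPI45	Pacifastin	2	canonical
PpSPI46	TIL	5	canonical
PpSPI47	TIL	5	canonical
PpSPI48	TIL	5	canonical
PpSPI49	TIL	5	canonical
PpSPI50	TIL	5	canonical
PpSPI51	Kunitz_BPTI	3	canonical
PpSPI52	Kunitz_BPTI	3	canonical
PpSPI53	Kunitz_BPTI	3	canonical
PpSPI54	Kunitz_BPTI	11	canonical
PpSPI54	WAP	1	canonical
PpSPI55	A2M	1	A2M
PpSPI56	A2M	1	A2M
PpSPI57	A2M	1	A2M
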