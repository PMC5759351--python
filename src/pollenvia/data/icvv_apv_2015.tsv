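plot_code	cultivar	main_use	skin_color	apv_mean	apv_sd	rating
01GRAJ007E	Corinto Bianco	W	Green yellow	14.15	1.28	Very low
01GRAJ018K	Flot Rouge	W	Blue black	35.10	11.05	Low
01GRAJ010A	Planta Mula	W/T	Blue black	44.87	6.53	Low
01GRAJ022H	Molar	W	Blue black	45.42	9.82	Low
01GRAJ021K	Tempranillo Tinto	W/T	Blue black	49.93	0.79	Low
01GRAJ015L	Vermentino	W/T	Green yellow	49.94	3.16	Low
01GRAJ012D	Garganega	W/T	Green yellow	52.90	3.59	Medium
01GRAJ015D	Tempranillo Blanco	W/T	Green yellow	57.26	6.89	Medium
01GRAJ020H	Mollar Cano	W/T	Blue black	57.89	1.77	Medium
01GRAJ015H	Trebbiano Toscano	W	Green yellow	58.55	14.91	Medium
01GRAJ010F	Albillo Real	W	Green yellow	60.38	9.67	Medium
01GRAJ013L	Muscat a Petits Grains Blancs	W/T	Green yellow	61.9	17.47	Medium
01GRAJ019G	Trousseau Noir	W	Dark red violet	62.95	24.9	Medium
01GRAJ011J	Vijiriega Común	W	Green yellow	65.52	0.82	Medium
01GRAJ014D	Parellada	W	Green yellow	66.81	4.36	Medium
01GRAJ007I	Dominga	W/T	Green yellow	67.69	28.24	Medium
01GRAJ013E	Maturana Blanca	W	Green yellow	68.37	14.33	Medium
01GRAJ020I	Ondarrabi Beltza	W/T	Blue black	68.76	19.75	Medium
01GRAJ019A	Jacquez	W	Blue black	69.80	7.10	Medium
01GRAJ010H	Aligote	W	Green yellow	69.99	3.98	Medium
01GRAJ011A	Cayetana Blanca	W/T	Green yellow	70.82	0.54	Medium
01GRAJ022E	Schiava Grossa	W/T	Blue black	75.52	1.19	High
01GRAJ020G	Negral	W	Blue black	76.48	2.56	High
01GRAJ021J	Syrah	W	Blue black	77.33	0.53	High
01GRAJ014L	Semillon	W	Green yellow	78.09	1.44	High
01GRAJ017F	Beba Roja	W/T	Red	79.00	2.46	High
01GRAJ017A	Alvarelhao	W	Blue black	80.51	14.82	High
01GRAJ015B	Alarije	W	Green yellow	80.87	7.65	High
01GRAJ009K	Naparo	T	Red	81.21	16.76	High
01GRAJ020F	Icod de los Vinos	W	Blue black	81.39	1.40	High
01GRAJ010C	Ruby Seedless	T	Rose	81.49	1.29	High
01GRAJ015K	Verdil	W	Green yellow	82.70	0.00	High
01GRAJ018A	Branco Escola	W	Blue black	82.71	8.43	High
01GRAJ014E	Pedro Ximenes	W	Green yellow	82.88	1.22	High
01GRAJ016D	Xarello	W	Green yellow	83.43	1.44	High
01GRAJ019L	Listán Prieto	W	Blue black	83.53	4.01	High
01GRAJ020C	Moravia Agria	W	Blue black	83.69	1.25	High
01GRAJ008A	Pardillo	W	Green yellow	83.82	1.13	High
01GRAJ007G	Afus Ali	W/T	Green yellow	84.74	5.66	High
01GRAJ014A	Palomino de Jerez	W	Green yellow	85.37	5.05	High
01GRAJ021D	Rubired	W/T	Blue black	85.59	10.00	High
01GRAJ012K	Alcanon	W	Green yellow	86.00	3.54	High
01GRAJ012F	Garrido Fino	W/T	Green yellow	86.30	2.95	High
01GRAJ008D	Muscat Ottonel	W/T	Green yellow	86.95	5.68	High
01GRAJ022A	Graciano	W	Blue black	87.07	6.89	High
01GRAJ021I	Sumoll	W	Blue black	87.40	7.99	High
01GRAJ011E	Chardonnay Blanc	W	Green yellow	87.55	0.56	High
01GRAJ007C	Beba	W/T	Green yellow	87.65	2.04	High
01GRAJ013G	Morio Muskat	W	Green yellow	87.83	3.25	High
01GRAJ014G	Cornichon Blanc	W/T	Green yellow	88.10	1.61	High
01GRAJ012B	Colombard	W/T	Green yellow	88.40	3.35	High
01GRAJ018F	Gamay Noir	W	Blue black	88.43	9.43	High
01GRAJ020B	Monastrell	W/T	Blue black	89.02	0.68	High
01GRAJ008J	Quiebratinajas Blanco	T	Red	89.53	10.68	High
01GRAJ011H	Siria	W	Green yellow	89.53	2.90	High
01GRAJ017E	Valenci Tinto	W/T	Blue black	89.98	1.43	High
01GRAJ013H	Muscat Hamburg	W/T	Green yellow	90.06	0.05	Very high
01GRAJ015C	Silvaner Gruen	W	Green yellow	90.66	1.88	Very high
01GRAJ018E	Tinto Velasco	W	Blue black	90.94	2.12	Very high
01GRAJ019J	Mencía	W	Blue black	91.35	0.63	Very high
01GRAJ007J	Mantuo	W/T	Green yellow	91.56	10.21	Very high
01GRAJ016L	Trepat	W	Dark red violet	91.66	0.62	Very high
01GRAJ012G	Gewuerztraminer	W	Green yellow	91.87	5.06	Very high
01GRAJ020D	Aramon Noir	W/T	Blue black	92.02	0.08	Very high
01GRAJ012L	Palomino Fino	W	Blue black	92.07	2.88	Very high
01GRAJ009E	Cardinal	W/T	Red	92.45	7.33	Very high
01GRAJ013B	Airen	W/T	Green yellow	92.66	1.96	Very high
01GRAJ008I	Planta Nova	W/T	Green yellow	92.81	4.52	Very high
01GRAJ022G	Valenci Tinto	W/T	Blue black	92.93	0.42	Very high
01GRAJ009C	Alphonse Lavallee	W/T/R	Dark red violet	92.99	1.03	Very high
01GRAJ016G	Alicante Henri Bouschet	W	Blue black	93.01	5.48	Very high
01GRAJ021E	Ruby Cabernet	W/T	Blue black	93.07	0.33	Very high
01GRAJ016F	Alfrocheiro	W	Blue black	93.38	0.38	Very high
01GRAJ016J	Barbera Nera	W	Blue black	93.62	1.87	Very high
01GRAJ007H	Delight	T	Green yellow	93.71	2.45	Very high
01GRAJ017C	Cabernet Sauvignon	W	Blue black	94.04	2.10	Very high
01GRAJ007L	Rey	W/T	Green yellow	94.25	1.58	Very high
01GRAJ014I	Planta Fina	W/T	Green yellow	94.33	0.96	Very high
01GRAJ007A	Aledo	T	Green yellow	94.55	1.08	Very high
01GRAJ007F	Cornichón Blanco Falso	W/T	Green yellow	94.74	1.65	Very high
01GRAJ019B	Moristel	W	Blue black	94.87	1.28	Very high
01GRAJ014J	Riesling Weiss	W	Green yellow	95.13	3.21	Very high
01GRAJ015G	Trajadura	W	Green yellow	95.25	0.35	Very high
01GRAJ017G	Carnelian	W	Blue black	95.28	0.77	Very high
01GRAJ013A	Loureiro Blanco	W	Green yellow	95.33	0.83	Very high
01GRAJ018C	Fogoneau	W	Blue black	95.36	1.81	Very high
01GRAJ020J	Graciano	W	Blue black	95.38	0.88	Very high
01GRAJ019I	Mencía	W	Blue black	95.52	0.63	Very high
01GRAJ011K	Verdejo Blanco	W	Green yellow	95.53	2.31	Very high
01GRAJ012H	Siria	W	Green yellow	95.57	1.57	Very high
01GRAJ009F	Cinsaut	W/T	Blue black	95.70	0.25	Very high
01GRAJ011I	Clairette Blanche	W/T	Green yellow	95.71	0.36	Very high
01GRAJ021H	Vinhao	W	Blue black	95.73	0.10	Very high
01GRAJ017J	Centurion	W	Blue black	95.93	0.68	Very high
01GRAJ011L	Folle Blanche	W	Green yellow	95.96	2.62	Very high
01GRAJ018D	Forcallat Tinta	W	Blue black	96.12	1.42	Very high
01GRAJ015E	Turruntés	W	Green yellow	96.21	0.35	Very high
01GRAJ021B	Pinot	W	Blue black	96.48	4.38	Very high
01GRAJ020L	Bouschet Petit	W	Blue black	96.72	0.06	Very high
01GRAJ022F	Valdiguie	W	Blue black	96.82	1.27	Very high
01GRAJ017D	Borracal	W	Blue black	96.84	1.45	Very high
01GRAJ014K	Sauvignon Blanc	W	Green yellow	96.97	2.05	Very high
01GRAJ020K	Castelao	W	Blue black	97.08	0.34	Very high
01GRAJ016K	Bobal	W	Blue black	97.09	0.03	Very high
01GRAJ010J	Auxerrois	W	Green yellow	97.23	0.16	Very high
01GRAJ014F	Zalema	W	Green yellow	97.33	0.46	Very high
01GRAJ010E	Alvarinho	W	Green yellow	97.50	0.90	Very high
01GRAJ017B	Cabernet Franc	W	Blue black	97.74	0.50	Very high
01GRAJ008F	Muskat Usbekistanskii	T	Green yellow	97.80	1.37	Very high
01GRAJ016I	Aubun	W	Blue black	98.05	1.87	Very high
01GRAJ021C	Cuelga	W	Green yellow	98.25	0.54	Very high
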