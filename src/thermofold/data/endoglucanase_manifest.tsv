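pdb_id	chain	label	fold	family	organism	length_reported
2zum		thermophile	(a/b)8	GH5/GH44	Pyrococcus horikoshii	458
1ece		thermophile	(a/b)8	GH5/GH44	Acidothermus cellulolyticus	358
1edg		thermophile	(a/b)8	GH5/GH44	Clostridium cellulolyticum	380
1cec		thermophile	(a/b)8	GH5/GH44	Clostridium thermocellum	343
1g0c		thermophile	(a/b)8	GH5/GH44	Bacillus sp. kas-635	364
1h1n		thermophile	(a/b)8	GH5/GH44	Thermoascus auranticus	305
3ii1		thermophile	(a/b)8	GH5/GH44	uncultured bacterium	535
2e4t		thermophile	(a/b)8	GH5/GH44	Clostridium thermocellum	509
3l55		mesophile	(a/b)8	GH5/GH44	Prevotella bryantii	353
7a3h		mesophile	(a/b)8	GH5/GH44	Bacillus agaradhaerens	303
1egz		mesophile	(a/b)8	GH5/GH44	Erwinia chrysanthemi	291
3ik2		mesophile	(a/b)8	GH5/GH44	Clostridium acetobutylicum	512
1ojj		thermophile	beta-jelly	GH7/GH12	Humicola insolens	402
1olr		thermophile	beta-jelly	GH7/GH12	Humicola grisea	224
2bw8		thermophile	beta-jelly	GH7/GH12	Rhodotermus marinus	227
3ovw		thermophile	beta-jelly	GH7/GH12	Fusarium oxysporum	411
2nlr		mesophile	beta-jelly	GH7/GH12	Streptomyces lividans	234
1oa2		mesophile	beta-jelly	GH7/GH12	Hypocrea jecorina	218
2jen		mesophile	beta-jelly	GH7/GH12	Bacillus licheniformis	261
1ks5		mesophile	beta-jelly	GH7/GH12	Aspergillus niger	223
1kwf		thermophile	(a/a)6	GH8/GH48/GH9	Clostridium thermocellum NCIB	363
1clc		thermophile	(a/a)6	GH8/GH48/GH9	Clostridium thermocellum	639
3gzk		thermophile	(a/a)6	GH8/GH48/GH9	Acyclobacillus acidocaldarius	537
1l1y		thermophile	(a/a)6	GH8/GH48/GH9	Clostridium thermocellum F7	678
1tf4		thermophile	(a/a)6	GH8/GH48/GH9	Thermobifida fusca	605
1wzz		mesophile	(a/a)6	GH8/GH48/GH9	Gluconacebacter xylinus	334
1ks8		mesophile	(a/a)6	GH8/GH48/GH9	Nasutitermes takasagoensis	433
1g87		mesophile	(a/a)6	GH8/GH48/GH9	Clostridium cellulolyticum	614
1ia6		mesophile	(a/a)6	GH8/GH48/GH9	Clostridium cellulolyticum	441
1g9g		mesophile	(a/a)6	GH8/GH48/GH9	Clostridium cellulolyticum	629
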