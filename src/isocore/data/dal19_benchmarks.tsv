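# Published best-match alignment records of assembled transcripts against the six
# cloned, Sanger-verified DAL19 isoform references (four long isoforms shown).
# similarity = printed score; evaluable = 1 when the score is fully determined by
# the CIGAR and reference length alone (only M and clip ops, or pure-indel CIGARs,
# under zero substitution mismatches). Rows with evaluable = 0 would need the
# unpublished substitution counts of their alignments and are excluded from exact checks.
reference	reference_length	assembly	similarity	cigar	evaluable
DAL19_αψδ	842	Oases	0.77	103S305M1D347M405S	1
DAL19_αψγ	813	Oases	0.87	103S13M1I291M1D241M105I267M139S	0
DAL19_βψδ	1095	Oases	0.80	872M405S	1
DAL19_βψγ	1067	Oases	0.97	1033M139S	1
DAL19_αψδ	842	Trinity	0.92	267S774M62S	1
DAL19_αψγ	813	Trinity	0.92	267S746M142S	1
DAL19_βψδ	1095	Trinity	0.68	274S767M62S	0
DAL19_βψγ	1067	Trinity	0.39	7M1I1M1I23M2I12M4D234M2I3M1D7M1D16M1D2M1I209M310S	0
DAL19_αψδ	842	cortexpy/kallisto	1.00	110S842M52S	1
DAL19_αψγ	813	cortexpy/kallisto	1.00	110S13M1I800M139S	1
DAL19_βψδ	1095	cortexpy/kallisto	0.92	1008M52S	1
DAL19_βψγ	1067	cortexpy/kallisto	0.45	177S31M6D41M2D4M1D4M5I2M4I3M1I8M2I10M3I5M3I2M1I35M2I8M2D1M2D472M524S	0
DAL19_αψδ	842	Nine bud samples	1.00	81S842M52S	1
DAL19_αψγ	813	Nine bud samples	1.00	81S13M1I800M69S	1
DAL19_βψδ	1095	Nine bud samples	0.96	1050M12S	1
DAL19_βψγ	1067	Nine bud samples	0.86	920M	1
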