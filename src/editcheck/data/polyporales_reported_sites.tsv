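# Published per-sample outcomes of re-filtering previously reported candidate
# RNA-editing sites in five wood-decay Polyporales species (vegetative mycelium,
# grown on aspen, pine or spruce for 5/10/30 days).  Columns: candidate sites
# entering filtering; sites with the matching variant in the gDNA read
# alignment; sites absent when the RNA reads were re-aligned with a newer
# spliced aligner; sites whose polymorphic RNA reads match raw gDNA reads
# despite no alignment at the position; sites attributed to different DNA/RNA
# source isolates.  For Antrodia sinuosa (DNA and RNA from different strains)
# the last two columns were published as complementary ranges and such rows are
# not single-valued.
species	sample_id	n_reported	n_dna_match	n_absent_realignment	n_pooled_match	n_retained
Daedalea quercina L-15889	Aspen-5D	435	421	13	0	1
Daedalea quercina L-15889	Pine-5D	355	347	8	0	0
Daedalea quercina L-15889	Spruce-5D	365	356	8	0	1
Fomitopsis pinicola FP-58527 SS1	Aspen-5D	1568	1510	45	13	0
Fomitopsis pinicola FP-58527 SS1	Pine-5D	1761	1690	53	18	0
Fomitopsis pinicola FP-58527 SS1	Pine-10D	753	716	27	9	1
Fomitopsis pinicola FP-58527 SS1	Pine-30D	1067	1022	34	11	0
Fomitopsis pinicola FP-58527 SS1	Spruce-5D	1288	1244	32	12	0
Fomitopsis pinicola FP-58527 SS1	Spruce-10D	901	863	33	5	0
Fomitopsis pinicola FP-58527 SS1	Spruce-30D	1098	1051	38	9	0
Laetiporus sulphureus 93-53	Aspen-5D	1328	1297	26	5	0
Laetiporus sulphureus 93-53	Pine-5D	1339	1314	21	4	0
Laetiporus sulphureus 93-53	Spruce-5D	1304	1282	19	3	0
Wolfiporia cocos MD-104 SS10	Aspen-5D	184	148	35	0	1
Wolfiporia cocos MD-104 SS10	Pine-5D	212	173	38	1	0
Wolfiporia cocos MD-104 SS10	Spruce-5D	195	153	42	0	0
Antrodia sinuosa	Aspen-5D	1141	698	0	139-304	139-304
Antrodia sinuosa	Pine-5D	1504	923	0	229-352	229-352
Antrodia sinuosa	Spruce-5D	936	568	0	110-258	110-258
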