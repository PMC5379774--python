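# Published per-transition summary statistics of interactome rewiring across
# ten developmental transitions of human blood cells (classical hematopoiesis
# hierarchy), used as the worked example for the transition-table statistics.
# delta_n / sigma_delta_n: mean +/- sd of the net interaction-count difference
#   between all samples of the two cell types.
# p_rew: mean Jaccard distance of edge sets over inter-group sample pairs.
# obs_s / obs_all: minimum significant observation count / number of pairwise
#   comparisons.  rew_plus / rew_minus: significant emerging / vanishing events.
transition	delta_n	sigma_delta_n	p_rew	obs_s	obs_all	rew_plus	rew_minus
HSC->MPP	10321	31944	0.372	15	18	311	123
MPP->CMP	5698	10558	0.278	9	9	856	423
MPP->CLP	-32173	33402	0.455	15	15	1	705
CMP->MEP	513	9254	0.261	8	12	3955	2532
CMP->GMP	3796	7169	0.256	6	9	8468	5556
MEP->EB	-6441	29842	0.348	20	28	3021	4146
MEP->MK	14831	12126	0.293	12	20	10574	3848
GMP->N	-54044	11225	0.585	24	30	3895	41599
GMP->M	-7517	6995	0.337	10	15	15763	21407
CLP->CD4	40898	37343	0.512	30	40	17181	1919
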