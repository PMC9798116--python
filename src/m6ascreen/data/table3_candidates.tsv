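gene_symbol	level_inoa_pct	level_oa_pct	quantity_inoa_oa	expr_fc_hp_oa	expr_fc_soma_oa	printed_evidence
MITF	6.80	19.40	Up	↑↑*	↑	No (i)
PUM1	6.80	18.40	Up	↑↑*	↑	No (i)
NPPB	35.10	78.50	Up*	↑	↑↑*	No (ii)
CLEC7A	32.30	66.00	Down	↓	↑	No (iii)
GRB10	20.10	40.40	Down	↑	↓	No (iii)
VSTM5	20.60	55.70	Down	↑	↓	No (iii)
ARF1	19.60	41.20	Down	↑	↓	No (iii)
CCDC61	15.70	34.30	Down	↑*	↑	No (iii)
CTXN2	21.80	50.80	Down*	↓*	↓↓	Yes (iv)
ANKRD60	28.50	64.10	Down*	↓↓*	↓↓	Yes (iv)
BDNF	32.70	67.50	Down*	↓	↓*	Yes (v)
TMEM38B	14.40	36.20	Down*	↓	↓↓*	Yes (v)
RPL3L	27.20	55.00	Down*	↓	↓*	Yes (v)
C22orf42	35.60	72.60	Down*	↓↓	↓↓*	Yes (v)
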