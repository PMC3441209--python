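target	per_residue_mcc	pore_helices_observed	pore_helices_predicted	topology_correct	topology_over_under	stoichiometry_observed	stoichiometry_predicted
1E12_A	0.04	4	2	1	0	1	1
1FFT_A	0.28	3	3	0	3	1	1
1KQG_B	-0.42	1	0	0	0	6	6
1KQG_C	0.03	2	0	1	0	6	5
1L7V_B	0.63	2	2	0	1	2	1
1LDI_A	0.41	5	2	1	0	1	3
1LNQ_A	0.76	1	0	1	0	4	4
1P7B_A	0.52	1	1	1	0	4	4
1PW4_A	0.50	7	3	1	0	1	1
1R3J_C	0.54	1	0	1	0	4	6
1T9Y_A	0.31	6	2	0	-4	1	1
1XL6_A	0.51	1	1	1	0	4	4
1XME_A	0.27	3	3	1	0	1	1
1XQF_A	0.52	5	4	0	-1	1	1
1Z98_A	0.35	3	3	1	0	1	1
1ZLL_E	0.00	1	0	0	0	5	3
2AHY_A	0.52	1	0	1	0	4	5
2B2F_A	0.49	4	3	0	-2	1	1
2BG9_A	0.15	1	1	1	0	5	2
2BG9_E	0.37	1	1	1	0	5	2
2C3E_A	-0.10	6	3	0	-2	1	1
2C8L_A	0.37	4	3	1	0	1	1
2D57_A	0.28	4	3	1	0	1	1
2F2B_A	0.05	3	1	1	0	1	3
2GFP_A	0.24	6	2	1	0	1	1
2HYD_A	0.22	4	1	0	-1	2	2
2OAR_A	0.00	1	1	1	0	5	3
2OAU_A	0.11	1	0	1	0	7	4
2ONK_C	0.49	3	1	1	0	2	2
2QFI_A	0.26	2	1	1	0	2	3
2QKS_A	0.44	1	1	1	0	4	4
2QTS_A	0.50	1	1	1	0	3	5
2R6G_F	0.33	2	1	1	0	2	2
2R6G_G	0.07	3	1	1	0	2	1
2RDD_B	-0.61	1	0	0	0	3	5
2W2E_A	0.38	4	3	1	0	1	1
2ZW3_A	-0.36	1	0	1	0	6	3
3B8C_A	0.45	5	3	1	0	1	1
3B9W_A	0.46	5	4	1	0	1	1
3BEH_A	0.22	1	0	0	-1	4	2
3C02_A	0.37	4	4	1	0	1	1
3DDL_A	0.11	4	2	1	0	1	1
3DHW_A	0.20	2	1	1	0	2	2
3EAM_A	0.30	1	0	0	-1	5	3
3GIA_A	0.32	4	3	1	0	1	1
3H9V_A	0.13	2	1	1	0	3	4
3HD6_A	0.50	4	4	1	0	1	1
3K3F_A	0.44	4	2	1	0	1	1
3KG2_A	0.37	1	1	0	1	4	1
3MKT_A	0.32	5	4	1	0	1	1
3O0R_B	0.11	5	0	1	0	1	1
3P5N_A	0.10	4	3	1	0	1	1
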