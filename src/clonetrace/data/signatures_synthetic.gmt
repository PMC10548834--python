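CD8_T_cells	immune	G0015	G0123	G0163	G0173	G0192	G0196	G0225	G0268	G0274	G0294	G0301	G0396	G0401	G0472	G0487
NK_cells	immune	G0050	G0076	G0082	G0136	G0176	G0243	G0296	G0327	G0332	G0343	G0369	G0435	G0437	G0458	G0473
B_cells	immune	G0029	G0053	G0108	G0179	G0226	G0243	G0263	G0291	G0328	G0368	G0385	G0391	G0403	G0482	G0490
CD4_T_cells	immune	G0036	G0037	G0131	G0151	G0159	G0185	G0215	G0253	G0272	G0297	G0298	G0364	G0373	G0424	G0493
Fibroblasts	stroma	G0001	G0018	G0033	G0040	G0069	G0099	G0163	G0181	G0194	G0219	G0258	G0275	G0369	G0439	G0467
Endothelial_cells	stroma	G0029	G0073	G0118	G0146	G0210	G0217	G0249	G0253	G0257	G0293	G0352	G0449	G0476	G0486	G0493
Pericytes	stroma	G0065	G0109	G0121	G0147	G0157	G0244	G0260	G0261	G0313	G0323	G0337	G0363	G0387	G0439	G0473
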