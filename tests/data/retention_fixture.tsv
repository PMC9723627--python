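intron_id	irratio	intron_depth	coverage_fraction	psi5	psi3	host_fpkm	length	expected
fx_00	0.25	20.0	0.95	0.95	0.95	5.0	500	retained
fx_01	0.25	20.0	0.95	0.85	0.95	5.0	500	ambiguous
fx_02	0.25	20.0	0.95	0.95	0.85	5.0	500	ambiguous
fx_03	0.25	20.0	0.95	0.95	0.95	0.5	500	ambiguous
fx_04	0.25	20.0	0.95	0.95	0.95	5.0	12000	ambiguous
fx_05	0.005	3.0	1.0	0.95	0.95	5.0	9999	non_retained
fx_06	0.005	3.0	0.95	0.95	0.95	5.0	500	non_retained
fx_07	0.005	3.0	0.5	0.95	0.95	5.0	500	non_retained
fx_08	0.005	3.0	0.9	0.95	0.95	5.0	500	non_retained
fx_09	0.005	9.9	0.95	0.95	0.95	5.0	500	non_retained
fx_10	0.005	9.9	0.5	0.95	0.95	5.0	500	non_retained
fx_11	0.005	9.9	0.9	0.95	0.95	5.0	500	non_retained
fx_12	0.005	10.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_13	0.005	10.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_14	0.005	10.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_15	0.005	25.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_16	0.005	25.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_17	0.005	25.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_18	0.01	3.0	0.95	0.95	0.95	5.0	500	non_retained
fx_19	0.01	3.0	0.5	0.95	0.95	5.0	500	non_retained
fx_20	0.01	3.0	0.9	0.95	0.95	5.0	500	non_retained
fx_21	0.01	9.9	0.95	0.95	0.95	5.0	500	non_retained
fx_22	0.01	9.9	0.5	0.95	0.95	5.0	500	non_retained
fx_23	0.01	9.9	0.9	0.95	0.95	5.0	500	non_retained
fx_24	0.01	10.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_25	0.01	10.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_26	0.01	10.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_27	0.01	25.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_28	0.01	25.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_29	0.01	25.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_30	0.05	3.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_31	0.05	3.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_32	0.05	3.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_33	0.05	9.9	0.95	0.95	0.95	5.0	500	ambiguous
fx_34	0.05	9.9	0.5	0.95	0.95	5.0	500	ambiguous
fx_35	0.05	9.9	0.9	0.95	0.95	5.0	500	ambiguous
fx_36	0.05	10.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_37	0.05	10.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_38	0.05	10.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_39	0.05	25.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_40	0.05	25.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_41	0.05	25.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_42	0.1	3.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_43	0.1	3.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_44	0.1	3.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_45	0.1	9.9	0.95	0.95	0.95	5.0	500	ambiguous
fx_46	0.1	9.9	0.5	0.95	0.95	5.0	500	ambiguous
fx_47	0.1	9.9	0.9	0.95	0.95	5.0	500	ambiguous
fx_48	0.1	10.0	0.95	0.95	0.95	5.0	500	retained
fx_49	0.1	10.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_50	0.1	10.0	0.9	0.95	0.95	5.0	500	retained
fx_51	0.1	25.0	0.95	0.95	0.95	5.0	500	retained
fx_52	0.1	25.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_53	0.1	25.0	0.9	0.95	0.95	5.0	500	retained
fx_54	0.25	3.0	0.95	0.95	0.95	5.0	500	ambiguous
fx_55	0.25	3.0	0.5	0.95	0.95	5.0	500	ambiguous
fx_56	0.25	3.0	0.9	0.95	0.95	5.0	500	ambiguous
fx_57	0.25	9.9	0.95	0.95	0.95	5.0	500	ambiguous
fx_58	0.25	9.9	0.5	0.95	0.95	5.0	500	ambiguous
fx_59	0.25	9.9	0.9	0.95	0.95	5.0	500	ambiguous
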