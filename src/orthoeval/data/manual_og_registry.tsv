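og_id	complex
IFT_01	Intraflagellar transport complex
IFT_02	Intraflagellar transport complex
IFT_03	Intraflagellar transport complex
IFT_04	Intraflagellar transport complex
IFT_05	Intraflagellar transport complex
IFT_06	Intraflagellar transport complex
IFT_07	Intraflagellar transport complex
IFT_08	Intraflagellar transport complex
IFT_09	Intraflagellar transport complex
IFT_10	Intraflagellar transport complex
IFT_11	Intraflagellar transport complex
IFT_12	Intraflagellar transport complex
IFT_13	Intraflagellar transport complex
IFT_14	Intraflagellar transport complex
IFT_15	Intraflagellar transport complex
IFT_16	Intraflagellar transport complex
IFT_17	Intraflagellar transport complex
IFT_18	Intraflagellar transport complex
IFT_19	Intraflagellar transport complex
IFT_20	Intraflagellar transport complex
IFT_21	Intraflagellar transport complex
IFT_22	Intraflagellar transport complex
IFT_23	Intraflagellar transport complex
IFT_24	Intraflagellar transport complex
IFT_25	Intraflagellar transport complex
IFT_26	Intraflagellar transport complex
KT_01	Kinetochore
KT_02	Kinetochore
KT_03	Kinetochore
KT_04	Kinetochore
KT_05	Kinetochore
KT_06	Kinetochore
KT_07	Kinetochore
KT_08	Kinetochore
KT_09	Kinetochore
KT_10	Kinetochore
KT_11	Kinetochore
KT_12	Kinetochore
KT_13	Kinetochore
KT_14	Kinetochore
KT_15	Kinetochore
KT_16	Kinetochore
KT_17	Kinetochore
KT_18	Kinetochore
KT_19	Kinetochore
KT_20	Kinetochore
KT_21	Kinetochore
KT_22	Kinetochore
KT_23	Kinetochore
KT_24	Kinetochore
KT_25	Kinetochore
KT_26	Kinetochore
KT_27	Kinetochore
KT_28	Kinetochore
KT_29	Kinetochore
KT_30	Kinetochore
KT_31	Kinetochore
KT_32	Kinetochore
KT_33	Kinetochore
KT_34	Kinetochore
KT_35	Kinetochore
KT_36	Kinetochore
KT_37	Kinetochore
KT_38	Kinetochore
KT_39	Kinetochore
KT_40	Kinetochore
KT_41	Kinetochore
KT_42	Kinetochore
KT_43	Kinetochore
KT_44	Kinetochore
KT_45	Kinetochore
KT_46	Kinetochore
KT_47	Kinetochore
KT_48	Kinetochore
KT_49	Kinetochore
KT_50	Kinetochore
KT_51	Kinetochore
KT_52	Kinetochore
KT_53	Kinetochore
KT_54	Kinetochore
KT_55	Kinetochore
KT_56	Kinetochore
KT_57	Kinetochore
KT_58	Kinetochore
KT_59	Kinetochore
KT_60	Kinetochore
KT_61	Kinetochore
KT_62	Kinetochore
KT_63	Kinetochore
KT_64	Kinetochore
KT_65	Kinetochore
KT_66	Kinetochore
KT_67	Kinetochore
KT_68	Kinetochore
KT_69	Kinetochore
KT_70	Kinetochore
KT_71	Kinetochore
KT_72	Kinetochore
KT_73	Kinetochore
KT_74	Kinetochore
KT_75	Kinetochore
KT_76	Kinetochore
KT_77	Kinetochore
KT_78	Kinetochore
KT_79	Kinetochore
KT_80	Kinetochore
KT_81	Kinetochore
KT_82	Kinetochore
KT_83	Kinetochore
KT_84	Kinetochore
KT_85	Kinetochore
KT_86	Kinetochore
KT_87	Kinetochore
KT_88	Kinetochore
KT_89	Kinetochore
KT_90	Kinetochore
KT_91	Kinetochore
TAF_01	TBP-associated factors
TAF_02	TBP-associated factors
TAF_03	TBP-associated factors
TAF_04	TBP-associated factors
TAF_05	TBP-associated factors
TAF_06	TBP-associated factors
TAF_07	TBP-associated factors
TAF_08	TBP-associated factors
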