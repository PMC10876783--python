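query_id	subject_id	blastn_identity
q00	s00	98.852
q01	s01	96.583
q02	s02	95.385
q03	s03	93.401
q04	s04	91.993
q05	s05	90.369
q06	s06	89.742
q07	s07	88.569
q08	s08	85.909
q09	s09	85.461
q10	s10	83.441
q11	s11	80.812
q12	s12	81.45
q13	s13	77.502
q14	s14	76.408
q15	s15	76.426
q16	s16	74.416
q17	s17	72.682
q18	s18	72.593
q19	s19	70.732
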