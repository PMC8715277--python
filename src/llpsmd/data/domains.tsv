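# Domain annotations for the packaged sequences, 1-based inclusive intervals.
# Boundaries are approximate literature values except where a range is quoted
# directly in the study text. buried=1 marks structured regions whose residues
# get the 30% short-range interaction scale-down.
# Columns: seq_id  label  start  end  buried
FUS	PLD	1	165	0
FUS	RGG	166	267	0
FUS	RRM1	285	371	1
FUS	RGG	372	421	0
FUS	ZF	422	453	1
FUS	RGG	454	501	0
FUS	NLS	514	526	0
hnRNPA1	RRM1	14	97	1
hnRNPA1	RRM2	105	184	1
hnRNPA1	LCD	186	372	0
TDP43	NTD	1	76	1
TDP43	NLS	82	98	0
TDP43	RRM1	106	176	1
TDP43	RRM2	191	259	1
TDP43	PLD	274	414	0
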