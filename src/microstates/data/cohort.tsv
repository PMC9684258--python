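id	sex	age	seizure_frequency	semiology	aetiology	eeg_focus	outcome	lev_dose_mg	adverse_events
1	F	73	Yearly	FS with PA	Structural (Ischaemic Stroke)	Left TP	NSF<50	1000	No
2	M	36	Yearly	FTB	Structural (Ischaemic Stroke)	Right FT	NSF>50	1000	No
3	M	64	Monthly	FS with IA	Unknown	Right T	NSF<50	1000	Transient depressive symptoms
4	F	25	Yearly	FS with IA	Structural (Cavernous Malformation)	Right T	NSF>50	1000	No
5	F	20	Monthly	FS with IA/FTB	Unknown	Right T	NSF>50	1000	Irritability
6	M	69	Monthly	FS with IA	Unknown	Left T	NSF>50	2000	No
7	F	30	Yearly	FS with IA	Unknown	Right FT	NSF>50	2000	No
8	F	38	Monthly	FS with IA	Unknown	Right T	NSF>50	1000	No
9	F	69	Monthly	FS with IA/FTB	Structural/Infectious (History of HSV Encephalitis)	Left T	NSF<50	1000	Transient depressive symptoms
10	M	64	Yearly	FS with IA/FTB	Structural/Infectious (Cerebral Abscess)	Left T	NSF>50	1000	No
11	F	24	Monthly	FTB	Structural (Hippocampal Sclerosis)	Left T	NSF>50	1500	No
12	M	28	Monthly	FTB	Unknown	Right T	SF	1500	No
13	F	55	One episode	FS with IA/FTB	Unknown	Left T	SF	2000	No
14	M	26	Monthly	FTB	Unknown	Right FT	SF	1500	No
15	M	78	Five episodes	FS with IA	Unknown	Left T	SF	1000	No
16	F	58	One episode	FS with PA	Unknown	Right T	SF	1000	Drowsiness
17	M	47	Two episodes	FS with IA/FTB	Structural (Cerebral AVM)	Left T	SF	2000	No
18	F	77	Four episodes	FS with PA	Structural (Ischaemic Stroke)	Left T	SF	1000	No
19	M	75	One episode	FS with PA	Unknown	Left T	SF	1000	Nausea
20	F	24	Four episodes	FS with IA	Structural (Cavernous Malformation)	Left T	SF	1250	No
21	F	63	One episode	FS with IA	Structural (Cavernous Malformation)	Right T	SF	1000	No
22	M	20	Monthly	FTB	Unknown	Left T	SF	1000	No
23	F	86	Monthly	FS with PA	Structural (Meningioma)	Left TP	SF	1000	No
24	M	39	Yearly	FTB	Unknown	Right T	SF	1500	No
25	M	75	Yearly	FTB	Unknown	Right T	SF	1000	No
26	F	21	Yearly	FS with IA/FTB	Unknown	Left T	SF	750	No
27	F	24	Yearly	FTB	Unknown	Right T	SF	1000	No
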