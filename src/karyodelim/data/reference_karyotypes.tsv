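sample_id	taxon_label	n_count	structure	locality_id	reference	multivalents_observed
KL-49-97	P. emmeli	79	1L+1M	gnishik	This study	false
183A07	P. emmeli	ca79	1L+1M	sevan_lake	This study	false
146A08	P. emmeli	ca78	1L+1M	gnishik	This study	false
150A08	P. emmeli	78	1L+1M	gnishik	This study	false
152A08	P. emmeli	78	1L+1M	gnishik	This study	false
157A08	P. emmeli	78	1L+1M	gnishik	This study	false
158A08	P. emmeli	79	1L+1M	gnishik	This study	false
318A08	P. emmeli	78	1L+1M	gnishik	This study	false
319A08	P. emmeli	ca78	1L+1M	gnishik	This study	false
320A08	P. emmeli	77	1L+1M	gnishik	This study	false
321A08	P. emmeli	ca77	1L+1M	gnishik	This study	false
234K16A	P. emmeli	77	1L+1M	vayots_dzor	This study	false
243K16A	P. emmeli	77	1L+1M	sevan_madina	This study	false
584K15	P. emmeli	77	1L+1M	sevan_artanish	This study	false
022K19	P. ripartii ripartii	90	1L+1M	jirgatol	This study	false
Dan2001-13	P. ripartii paralcestis	ca90	1L+1M	ja_joor_pass	This study	false
198A08	P. ripartii kalashiani	ca90	1L+1M	shvanidzor	This study	false
201A08	P. ripartii kalashiani	ca90	1L+1M	shvanidzor	This study	false
209A08	P. ripartii kalashiani	ca90	1L+1M	shvanidzor	This study	false
E250	P. keleybaricus	ca86	1L+1M	keleybar_makidi	This study	false
E258	P. keleybaricus	ca86	1L+1M	keleybar_makidi	This study	false
E260	P. keleybaricus	86	1L+1M	keleybar_makidi	This study	false
E261	P. keleybaricus	ca86	1L+1M	keleybar_makidi	This study	false
E262	P. keleybaricus	86	1L+1M	keleybar_makidi	This study	false
E311	P. admetus	79	1L+0M	varzagan	This study	false
KL-34-96	P. admetus yeranyani	ca80	1L+0M	aragats	This study	false
KL-50-97	P. admetus yeranyani	79	1L+0M	aragats	This study	false
KL-67-97	P. admetus yeranyani	79	1L+0M	megri_lichk	This study	false
154A08	P. admetus yeranyani	79	1L+0M	gnishik	This study	false
211A08	P. admetus yeranyani	79	1L+0M	gyumarants	This study	false
KL-28-97	P. demavendi belovi	74	2L+2M	khosrov	This study	false
003A07	P. demavendi belovi	73	2L+2M	gnishik	This study	false
050A07	P. demavendi belovi	74	2L+2M	khosrov	This study	false
051A07	P. demavendi belovi	74	2L+2M	khosrov	This study	false
054A07	P. demavendi belovi	74	2L+2M	khosrov	This study	false
064A07	P. demavendi belovi	73	2L+2M	khosrov	This study	false
070A07	P. demavendi belovi	73	2L+2M	khosrov	This study	false
077A08	P. demavendi belovi	74	2L+2M	gnishik	This study	false
079A08	P. demavendi belovi	74	2L+2M	gnishik	This study	false
106A08	P. demavendi belovi	73	2L+2M	khosrov	This study	false
121A07	P. demavendi belovi	75	2L+2M	vohkchaberd	This study	false
2002Q479	P. demavendi belovi	ca73	2L+2M	khosrov	This study	false
138A07	P. demavendi antonius	ca72	2L+2M	sevan_lake	This study	false
140A07	P. demavendi antonius	71	2L+2M	sevan_lake	This study	false
151A07	P. demavendi antonius	71	2L+2M	sevan_lake	This study	false
184A07	P. demavendi antonius	ca73	2L+2M	sevan_lake	This study	false
192A07	P. demavendi antonius	71	2L+2M	sevan_lake	This study	false
195A07	P. demavendi antonius	ca71	2L+2M	sevan_lake	This study	false
KL-1996-34-1	P. eriwanensis	ca32	0L+0M	aragats	previous study	false
KL-1997-6-1	P. eriwanensis	ca34	0L+0M	garny	previous study	false
KL-1997-6-4	P. eriwanensis	ca31	0L+0M	garny	previous study	false
KL-1997-6-7	P. eriwanensis	34	0L+0M	garny	previous study	false
KL-1997-6-8	P. eriwanensis	ca34	0L+0M	garny	previous study	false
KL-1997-6-9	P. eriwanensis	33	0L+0M	garny	previous study	false
KL-1997-7	P. eriwanensis	29	0L+0M	garny	previous study	false
KL-1997-76-1	P. eriwanensis	34	0L+0M	gnishik	previous study	false
AD2001-Nr4	P. eriwanensis	ca30	0L+0M	geghadir	previous study	false
AD2001-008	P. eriwanensis	34	0L+0M	gnishik	previous study	false
001A07	P. eriwanensis	34	0L+0M	gnishik	previous study	false
002A07	P. eriwanensis	32	0L+0M	gnishik	previous study	false
004A07	P. eriwanensis	32	0L+0M	gnishik	previous study	false
004A09	P. eriwanensis	ca32	0L+0M	gnishik	previous study	false
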