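# Collecting sites of the karyotyped voucher specimens.  Coordinates for
# gnishik, sevan_* sites, vayots_dzor (Hermon), shvanidzor/gyumarants and
# keleybar_makidi are as published; the remaining sites carry approximate
# gazetteer coordinates (only the ids matter at the default merge radius 0).
locality_id	name	lat	lon
gnishik	Armenia, Gnishik	39.673	45.291
sevan_lake	Armenia, Sevan Lake (Artanish slopes)	40.468	45.306
sevan_madina	Armenia, Sevan Lake, Madina	40.472	45.257
sevan_artanish	Armenia, Sevan Lake, Artanish	40.472	45.317
vayots_dzor	Armenia, Vayots Dzor (Hermon)	39.902	45.442
jirgatol	Tajikistan, Jirgatol	39.20	71.20
ja_joor_pass	Armenia, Ja Joor pass	39.05	46.20
shvanidzor	Armenia, Shvanidzor	39.003	46.380
gyumarants	Armenia, Gyumarants	39.003	46.380
keleybar_makidi	Iran, Keleybar, Makidi	38.85	46.89
varzagan	Iran, Azerbaijan-e Sharqi, Varzagan	38.51	46.65
aragats	Armenia, Aragats	40.45	44.25
megri_lichk	Armenia, Megri, Lichk	38.95	46.15
khosrov	Armenia, Khosrov	39.96	44.90
vohkchaberd	Armenia, Vohkchaberd	40.12	44.63
garny	Armenia, Garny	40.12	44.73
geghadir	Armenia, Geghadir	40.15	44.60
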