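cAMP signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE000	SYNGENE001	SYNGENE002	SYNGENE003	SYNGENE004
ErbB signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE005	SYNGENE006	SYNGENE007	SYNGENE008	SYNGENE009
Calcium signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE010	SYNGENE011	SYNGENE012	SYNGENE013	SYNGENE014
Cytokine-cytokine receptor interaction	synthetic placeholder membership - replace with curated gene sets	SYNGENE015	SYNGENE016	SYNGENE017	SYNGENE018	SYNGENE019
Apoptosis	synthetic placeholder membership - replace with curated gene sets	SYNGENE020	SYNGENE021	SYNGENE022	SYNGENE023	SYNGENE024
JAK-STAT signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE025	SYNGENE026	SYNGENE027	SYNGENE028	SYNGENE029
Wnt signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE030	SYNGENE031	SYNGENE032	SYNGENE033	SYNGENE034
Hedgehog signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE035	SYNGENE036	SYNGENE037	SYNGENE038	SYNGENE039
PI3K-Akt signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE040	SYNGENE041	SYNGENE042	SYNGENE043	SYNGENE044
TGF-beta signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE045	SYNGENE046	SYNGENE047	SYNGENE048	SYNGENE049
Notch signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE050	SYNGENE051	SYNGENE052	SYNGENE053	SYNGENE054
RET signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE055	SYNGENE056	SYNGENE057	SYNGENE058	SYNGENE059
MAPK signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE060	SYNGENE061	SYNGENE062	SYNGENE063	SYNGENE064
p53 signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE065	SYNGENE066	SYNGENE067	SYNGENE068	SYNGENE069
mTOR signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE070	SYNGENE071	SYNGENE072	SYNGENE073	SYNGENE074
Ras signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE075	SYNGENE076	SYNGENE077	SYNGENE078	SYNGENE079
HIF-1 signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE080	SYNGENE081	SYNGENE082	SYNGENE083	SYNGENE084
Cell cycle	synthetic placeholder membership - replace with curated gene sets	SYNGENE085	SYNGENE086	SYNGENE087	SYNGENE088	SYNGENE089
VEGF signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE090	SYNGENE091	SYNGENE092	SYNGENE093	SYNGENE094
NF-kappa B signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE095	SYNGENE096	SYNGENE097	SYNGENE098	SYNGENE099
Estrogen signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE100	SYNGENE101	SYNGENE102	SYNGENE103	SYNGENE104
PPAR signaling pathway	synthetic placeholder membership - replace with curated gene sets	SYNGENE105	SYNGENE106	SYNGENE107	SYNGENE108	SYNGENE109
Focal adhesion	synthetic placeholder membership - replace with curated gene sets	SYNGENE110	SYNGENE111	SYNGENE112	SYNGENE113	SYNGENE114
Adherens junction	synthetic placeholder membership - replace with curated gene sets	SYNGENE115	SYNGENE116	SYNGENE117	SYNGENE118	SYNGENE119
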