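# Synthetic stand-in lookup table: 360 cortical regions (180 per hemisphere)
# assigned to the 7 canonical functional systems. Region labels are generic;
# this is not a real surface-overlap assignment.
region_label	hemisphere	network
L_ROI001	L	VN
L_ROI002	L	VN
L_ROI003	L	VN
L_ROI004	L	VN
L_ROI005	L	VN
L_ROI006	L	VN
L_ROI007	L	VN
L_ROI008	L	VN
L_ROI009	L	VN
L_ROI010	L	VN
L_ROI011	L	VN
L_ROI012	L	VN
L_ROI013	L	VN
L_ROI014	L	VN
L_ROI015	L	VN
L_ROI016	L	VN
L_ROI017	L	VN
L_ROI018	L	VN
L_ROI019	L	VN
L_ROI020	L	VN
L_ROI021	L	VN
L_ROI022	L	VN
L_ROI023	L	VN
L_ROI024	L	VN
L_ROI025	L	VN
L_ROI026	L	VN
L_ROI027	L	VN
L_ROI028	L	VN
L_ROI029	L	VN
L_ROI030	L	VN
L_ROI031	L	SN
L_ROI032	L	SN
L_ROI033	L	SN
L_ROI034	L	SN
L_ROI035	L	SN
L_ROI036	L	SN
L_ROI037	L	SN
L_ROI038	L	SN
L_ROI039	L	SN
L_ROI040	L	SN
L_ROI041	L	SN
L_ROI042	L	SN
L_ROI043	L	SN
L_ROI044	L	SN
L_ROI045	L	SN
L_ROI046	L	SN
L_ROI047	L	SN
L_ROI048	L	SN
L_ROI049	L	SN
L_ROI050	L	SN
L_ROI051	L	SN
L_ROI052	L	SN
L_ROI053	L	SN
L_ROI054	L	SN
L_ROI055	L	SN
L_ROI056	L	SN
L_ROI057	L	DAN
L_ROI058	L	DAN
L_ROI059	L	DAN
L_ROI060	L	DAN
L_ROI061	L	DAN
L_ROI062	L	DAN
L_ROI063	L	DAN
L_ROI064	L	DAN
L_ROI065	L	DAN
L_ROI066	L	DAN
L_ROI067	L	DAN
L_ROI068	L	DAN
L_ROI069	L	DAN
L_ROI070	L	DAN
L_ROI071	L	DAN
L_ROI072	L	DAN
L_ROI073	L	DAN
L_ROI074	L	DAN
L_ROI075	L	DAN
L_ROI076	L	DAN
L_ROI077	L	DAN
L_ROI078	L	DAN
L_ROI079	L	DAN
L_ROI080	L	VAN
L_ROI081	L	VAN
L_ROI082	L	VAN
L_ROI083	L	VAN
L_ROI084	L	VAN
L_ROI085	L	VAN
L_ROI086	L	VAN
L_ROI087	L	VAN
L_ROI088	L	VAN
L_ROI089	L	VAN
L_ROI090	L	VAN
L_ROI091	L	VAN
L_ROI092	L	VAN
L_ROI093	L	VAN
L_ROI094	L	VAN
L_ROI095	L	VAN
L_ROI096	L	VAN
L_ROI097	L	VAN
L_ROI098	L	VAN
L_ROI099	L	VAN
L_ROI100	L	VAN
L_ROI101	L	VAN
L_ROI102	L	LS
L_ROI103	L	LS
L_ROI104	L	LS
L_ROI105	L	LS
L_ROI106	L	LS
L_ROI107	L	LS
L_ROI108	L	LS
L_ROI109	L	LS
L_ROI110	L	LS
L_ROI111	L	LS
L_ROI112	L	LS
L_ROI113	L	LS
L_ROI114	L	LS
L_ROI115	L	LS
L_ROI116	L	LS
L_ROI117	L	LS
L_ROI118	L	LS
L_ROI119	L	LS
L_ROI120	L	LS
L_ROI121	L	FN
L_ROI122	L	FN
L_ROI123	L	FN
L_ROI124	L	FN
L_ROI125	L	FN
L_ROI126	L	FN
L_ROI127	L	FN
L_ROI128	L	FN
L_ROI129	L	FN
L_ROI130	L	FN
L_ROI131	L	FN
L_ROI132	L	FN
L_ROI133	L	FN
L_ROI134	L	FN
L_ROI135	L	FN
L_ROI136	L	FN
L_ROI137	L	FN
L_ROI138	L	FN
L_ROI139	L	FN
L_ROI140	L	FN
L_ROI141	L	FN
L_ROI142	L	FN
L_ROI143	L	FN
L_ROI144	L	FN
L_ROI145	L	FN
L_ROI146	L	FN
L_ROI147	L	FN
L_ROI148	L	DMN
L_ROI149	L	DMN
L_ROI150	L	DMN
L_ROI151	L	DMN
L_ROI152	L	DMN
L_ROI153	L	DMN
L_ROI154	L	DMN
L_ROI155	L	DMN
L_ROI156	L	DMN
L_ROI157	L	DMN
L_ROI158	L	DMN
L_ROI159	L	DMN
L_ROI160	L	DMN
L_ROI161	L	DMN
L_ROI162	L	DMN
L_ROI163	L	DMN
L_ROI164	L	DMN
L_ROI165	L	DMN
L_ROI166	L	DMN
L_ROI167	L	DMN
L_ROI168	L	DMN
L_ROI169	L	DMN
L_ROI170	L	DMN
L_ROI171	L	DMN
L_ROI172	L	DMN
L_ROI173	L	DMN
L_ROI174	L	DMN
L_ROI175	L	DMN
L_ROI176	L	DMN
L_ROI177	L	DMN
L_ROI178	L	DMN
L_ROI179	L	DMN
L_ROI180	L	DMN
R_ROI001	R	VN
R_ROI002	R	VN
R_ROI003	R	VN
R_ROI004	R	VN
R_ROI005	R	VN
R_ROI006	R	VN
R_ROI007	R	VN
R_ROI008	R	VN
R_ROI009	R	VN
R_ROI010	R	VN
R_ROI011	R	VN
R_ROI012	R	VN
R_ROI013	R	VN
R_ROI014	R	VN
R_ROI015	R	VN
R_ROI016	R	VN
R_ROI017	R	VN
R_ROI018	R	VN
R_ROI019	R	VN
R_ROI020	R	VN
R_ROI021	R	VN
R_ROI022	R	VN
R_ROI023	R	VN
R_ROI024	R	VN
R_ROI025	R	VN
R_ROI026	R	VN
R_ROI027	R	VN
R_ROI028	R	VN
R_ROI029	R	VN
R_ROI030	R	VN
R_ROI031	R	SN
R_ROI032	R	SN
R_ROI033	R	SN
R_ROI034	R	SN
R_ROI035	R	SN
R_ROI036	R	SN
R_ROI037	R	SN
R_ROI038	R	SN
R_ROI039	R	SN
R_ROI040	R	SN
R_ROI041	R	SN
R_ROI042	R	SN
R_ROI043	R	SN
R_ROI044	R	SN
R_ROI045	R	SN
R_ROI046	R	SN
R_ROI047	R	SN
R_ROI048	R	SN
R_ROI049	R	SN
R_ROI050	R	SN
R_ROI051	R	SN
R_ROI052	R	SN
R_ROI053	R	SN
R_ROI054	R	SN
R_ROI055	R	SN
R_ROI056	R	SN
R_ROI057	R	DAN
R_ROI058	R	DAN
R_ROI059	R	DAN
R_ROI060	R	DAN
R_ROI061	R	DAN
R_ROI062	R	DAN
R_ROI063	R	DAN
R_ROI064	R	DAN
R_ROI065	R	DAN
R_ROI066	R	DAN
R_ROI067	R	DAN
R_ROI068	R	DAN
R_ROI069	R	DAN
R_ROI070	R	DAN
R_ROI071	R	DAN
R_ROI072	R	DAN
R_ROI073	R	DAN
R_ROI074	R	DAN
R_ROI075	R	DAN
R_ROI076	R	DAN
R_ROI077	R	DAN
R_ROI078	R	DAN
R_ROI079	R	DAN
R_ROI080	R	VAN
R_ROI081	R	VAN
R_ROI082	R	VAN
R_ROI083	R	VAN
R_ROI084	R	VAN
R_ROI085	R	VAN
R_ROI086	R	VAN
R_ROI087	R	VAN
R_ROI088	R	VAN
R_ROI089	R	VAN
R_ROI090	R	VAN
R_ROI091	R	VAN
R_ROI092	R	VAN
R_ROI093	R	VAN
R_ROI094	R	VAN
R_ROI095	R	VAN
R_ROI096	R	VAN
R_ROI097	R	VAN
R_ROI098	R	VAN
R_ROI099	R	VAN
R_ROI100	R	VAN
R_ROI101	R	VAN
R_ROI102	R	LS
R_ROI103	R	LS
R_ROI104	R	LS
R_ROI105	R	LS
R_ROI106	R	LS
R_ROI107	R	LS
R_ROI108	R	LS
R_ROI109	R	LS
R_ROI110	R	LS
R_ROI111	R	LS
R_ROI112	R	LS
R_ROI113	R	LS
R_ROI114	R	LS
R_ROI115	R	LS
R_ROI116	R	LS
R_ROI117	R	LS
R_ROI118	R	LS
R_ROI119	R	LS
R_ROI120	R	LS
R_ROI121	R	FN
R_ROI122	R	FN
R_ROI123	R	FN
R_ROI124	R	FN
R_ROI125	R	FN
R_ROI126	R	FN
R_ROI127	R	FN
R_ROI128	R	FN
R_ROI129	R	FN
R_ROI130	R	FN
R_ROI131	R	FN
R_ROI132	R	FN
R_ROI133	R	FN
R_ROI134	R	FN
R_ROI135	R	FN
R_ROI136	R	FN
R_ROI137	R	FN
R_ROI138	R	FN
R_ROI139	R	FN
R_ROI140	R	FN
R_ROI141	R	FN
R_ROI142	R	FN
R_ROI143	R	FN
R_ROI144	R	FN
R_ROI145	R	FN
R_ROI146	R	FN
R_ROI147	R	FN
R_ROI148	R	DMN
R_ROI149	R	DMN
R_ROI150	R	DMN
R_ROI151	R	DMN
R_ROI152	R	DMN
R_ROI153	R	DMN
R_ROI154	R	DMN
R_ROI155	R	DMN
R_ROI156	R	DMN
R_ROI157	R	DMN
R_ROI158	R	DMN
R_ROI159	R	DMN
R_ROI160	R	DMN
R_ROI161	R	DMN
R_ROI162	R	DMN
R_ROI163	R	DMN
R_ROI164	R	DMN
R_ROI165	R	DMN
R_ROI166	R	DMN
R_ROI167	R	DMN
R_ROI168	R	DMN
R_ROI169	R	DMN
R_ROI170	R	DMN
R_ROI171	R	DMN
R_ROI172	R	DMN
R_ROI173	R	DMN
R_ROI174	R	DMN
R_ROI175	R	DMN
R_ROI176	R	DMN
R_ROI177	R	DMN
R_ROI178	R	DMN
R_ROI179	R	DMN
R_ROI180	R	DMN
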