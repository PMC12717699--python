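SYNSEN_UP	synthetic placeholder up-regulated set	SYNUP001	SYNUP002	SYNUP003	SYNUP004	SYNUP005	SYNUP006	SYNUP007	SYNUP008	SYNUP009	SYNUP010	SYNUP011	SYNUP012	SYNUP013	SYNUP014	SYNUP015	SYNUP016	SYNUP017	SYNUP018	SYNUP019	SYNUP020	SYNUP021	SYNUP022	SYNUP023	SYNUP024	SYNUP025	SYNUP026	SYNUP027	SYNUP028	SYNUP029	SYNUP030	SYNUP031	SYNUP032	SYNUP033
SYNSEN_DN	synthetic placeholder down-regulated set	SYNDN001	SYNDN002	SYNDN003	SYNDN004	SYNDN005	SYNDN006	SYNDN007	SYNDN008	SYNDN009	SYNDN010	SYNDN011	SYNDN012	SYNDN013	SYNDN014	SYNDN015	SYNDN016	SYNDN017	SYNDN018	SYNDN019	SYNDN020	SYNDN021	SYNDN022	SYNDN023	SYNDN024	SYNDN025	SYNDN026	SYNDN027	SYNDN028	SYNDN029	SYNDN030	SYNDN031	SYNDN032	SYNDN033	SYNDN034	SYNDN035	SYNDN036	SYNDN037	SYNDN038	SYNDN039	SYNDN040	SYNDN041	SYNDN042	SYNDN043	SYNDN044	SYNDN045	SYNDN046	SYNDN047	SYNDN048	SYNDN049	SYNDN050	SYNDN051	SYNDN052	SYNDN053	SYNDN054	SYNDN055	SYNDN056	SYNDN057	SYNDN058	SYNDN059	SYNDN060	SYNDN061	SYNDN062	SYNDN063	SYNDN064	SYNDN065	SYNDN066	SYNDN067
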