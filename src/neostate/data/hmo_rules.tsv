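substrate	enzyme_alternatives	transporter_alternatives	default_mode
2FL	GH95|GH29	FL1_Blon0341-0343|FL2_Blon2202-2204	enzyme_only
lactose	GH2	LacS	enzyme_and_transporter
fucose	FumC+FumD+FumE+FumF+FumG	FucP	enzyme_and_transporter
LNT	GH42|GH136	GltABC	enzyme_and_transporter
LNnT	GH20	Bbr_1554	enzyme_and_transporter
LNB	GH112	GltABC	enzyme_and_transporter
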