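clone_id	hcdr3_aa	lcdr3_aa
AR1	GSGGVDSIDA	GSYDNTYAGI
AR2	SADGYGWDTAGNMDA	GSIDSNYDGI
AR3	TAGTCTTSCNAGAYIDA	GGYDGSSAA
AR4	TTCSGSYGWCADSIDA	GAYDSSYIGI
AR5	SADSCATCATYPSEIDT	GSFDSSYVGM
AR6	SADSCATCATYPSEIDT	GSFDSSYVGM
AR7	SADSCATCATYPSEIDT	GSIDSNYDGI
AR8	SADSCATCATYPSEIDT	GSYDSSYVGL
AR9	SADSCATCATYPSEIDT	GSYDSSYDGV
AR10	SADSCATCATYPSEIDT	GSFDSSYTGI
AR11	SADSCATCATYPSEIDT	GSIDSRYVGI
AR12	SADSCATCATYPSEIDT	GSYDSSYVGYVGV
AR13	SADSCATCATYPSEIDT	GSYDNTYAGI
AR14	SADSCATCATYPSEIDT	GGYDSSSGA
AR15	SADSCATCATYPSEIDT	GAYDSSYIGI
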