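gene_id	name	accession	gene_class	go_terms
GRMZM2G174807	ZmPIP1;1	Q41870	PIP1
PLACEHOLDER_ZmPIP1;2	ZmPIP1;2		PIP1
GRMZM2G392975	ZmPIP1;3	AAK26754	PIP1
GRMZM2G392975	ZmPIP1;4	AAK26754	PIP1
GRMZM2G081843	ZmPIP1;5	AAK26756	PIP1
GRMZM2G136032	ZmPIP1;6	AAK26757	PIP1
GRMZM2G014914	ZmPIP2;1	AAK26758	PIP2
GRMZM2G092125	ZmPIP2;2	AAK26759	PIP2
GRMZM2G081192	ZmPIP2;3	AAK26760	PIP2
GRMZM2G154628	ZmPIP2;4	AAK26761	PIP2
GRMZM2G178693	ZmPIP2;5	AAD28761	PIP2
GRMZM2G047368	ZmPIP2;6	AAK26762	PIP2
AAK26763	ZmPIP2;7	AAK26763	PIP2
AAC09245	ZmTIP1;1	AAC09245	TIP
GRMZM2G168439	ZmTIP1;2	AAK26767	TIP
GRMZM2G027098	ZmTIP2;1	AAK26768	TIP
GRMZM2G056908	ZmTIP2;2	AAK26769	TIP
GRMZM2G125023	ZmTIP2;3	AAK26770	TIP
GRMZM2G305446	ZmTIP3;1	AAK26771	TIP
GRMZM2G103983	ZmTIP3;2	AAK26848	TIP
GRMZM2G103945	ZmTIP4;1		TIP
GRMZM2G108273	ZmTIP4;2	AAK26773	TIP
GRMZM2G146627	ZmTIP4;3		TIP
GRMZM2G093090	ZmTIP4;4	AAK26775	TIP
GRMZM2G041980	ZmNIP1;1	AAK26750	NIP
GRMZM2G028325	ZmNIP2;1	AAK26751	NIP
GRMZM2G137108	ZmNIP2;2	AAK26752	NIP
GRMZM2G081239	ZmNIP2;3	AAK26849	NIP
GRMZM2G176209	ZmNIP3;1	AAK26753	NIP
GRMZM2G000471	ZmNIP5;1		NIP
GRMZM2G113470	ZmSIP1;1		SIP
GRMZM2G060922	ZmSIP1;2		SIP
GRMZM2G175038	ZmSIP2;1		SIP
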