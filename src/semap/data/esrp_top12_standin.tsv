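name	pattern	source
ESRP_6mer_01	UGGUGG	esrp_selex
ESRP_6mer_02	GGUGGU	esrp_selex
ESRP_6mer_03	GUGGUG	esrp_selex
ESRP_6mer_04_standin	UGGUGU	esrp_selex
ESRP_6mer_05_standin	GUGGUU	esrp_selex
ESRP_6mer_06_standin	UUGGUG	esrp_selex
ESRP_6mer_07_standin	UGGUUG	esrp_selex
ESRP_6mer_08_standin	UGUGGU	esrp_selex
ESRP_6mer_09_standin	GGUUGG	esrp_selex
ESRP_6mer_10_standin	UGGGUG	esrp_selex
ESRP_6mer_11_standin	GUUGGU	esrp_selex
ESRP_6mer_12_standin	GGUGUU	esrp_selex
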