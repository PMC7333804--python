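# ATC code -> medication class grouping table.
# Covers the drug lists of the five investigated classes; ACE inhibitors and
# ARBs collapse into the composite class "acei_arb".  Edit or extend freely.
atc_code	class
A10BA02	metformin
A10BB01	su
A10BB03	su
A10BB09	su
A10BB12	su
A10AB01	insulin
A10AB04	insulin
A10AB05	insulin
A10AB06	insulin
A10AC01	insulin
A10AD01	insulin
A10AD04	insulin
A10AD05	insulin
A10AE04	insulin
A10AE05	insulin
A10AE06	insulin
C09AA01	acei_arb
C09AA02	acei_arb
C09AA03	acei_arb
C09AA04	acei_arb
C09AA05	acei_arb
C09AA06	acei_arb
C09CA01	acei_arb
C09CA03	acei_arb
C09CA04	acei_arb
C09CA06	acei_arb
C09CA07	acei_arb
C09CA08	acei_arb
C10AA01	statin
C10AA03	statin
C10AA04	statin
C10AA05	statin
C10AA07	statin
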