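ref_id	label	sequence
REF_I_1	I	SFRQETIYWRKYGQKSGLLQVKQLTCVGTSCKAYTKYIFMINEAPAMNWYFKNHRHPLLQVF
REF_I_2	I	SFRQETIYWRKYGQKSGLLQVKQLTCMGTSCKDVTKYIQMDNEAPAMNWYFKNHRHPLLQVF
REF_IIa_1	IIa	DKEYRISQWRKYGQKRKDAVKWGAFCFMSEYCYRENQIRDGFKASPKGYTKDDQHSHIFQWKD
REF_IIa_2	IIa	DKEYRWSQWRKYGQKRKDAVKAGAFCFMSEYCYRENQIRDGFVASPDGQTKDDQHSHIFQWKD
REF_IIb_1	IIb	WSLGGMVGWRKYGQKESWDLLDSAYCNTMECWTNEFSEERPGSEVEWYIDFESHEHVDVMAD
REF_IIb_2	IIb	WSLGGMVMWRKYGQKESWFLEDSAYCNTMECWTNEFSEERPGSEVEWYIDFESHEHLDVAAD
REF_IIc_1	IIc	VYQLTTYTWRKYGQKRAPEVWTWENCLYYDPCLYYAGRPDYLRDMRGMRSKKMTHKHGGMIAR
REF_IIc_2	IIc	VYQLTTYTWRKYGQKRAPEQWTWENCLYYYPCLYYAGTPDYLRDMRGMRRKKMTHKHIGMIAR
REF_IId_1	IId	SFYWKKPDWRKYGQKGQEWLAGAGGCSNAFCSFVDNYALARNTDIVSVRTILTGHIHVIIATG
REF_IId_2	IId	SSYWKKPDWRKYGQKGQEWLAGAGGCSNAFCNFVDNYALARNTIVVSVRTILTGHIHVIQATG
REF_IIe_1	IIe	VRYSNQYIWRKYGQKVFPQKDDNDPCMLENFCVKRQYDMNMSVTTPWNFAQRNYHQHKTYGDW
REF_IIe_2	IIe	GELSNQYIWRKYGQKVFPQKVDNDPCMLENFCVKRQYDVNMSVTTPWNFAQRNYHQHKTYGDW
REF_III_1	III	QDLTAKPAWRKYGQKKWNGERANAMCDNADMNECERATRVQPRFWSITMYWSFKEWRHKCIGQEAE
REF_III_2	III	QDLGAKPAWRKYGQKKWNGERANAMCDNASMNECERATRLQRRFWSITMYWSFKEWRHDCIGQEAE
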