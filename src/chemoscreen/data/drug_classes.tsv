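drug	class
Bendamustine	ALKYLATING
Carboplatin	ALKYLATING
Carmustine	ALKYLATING
Chlorambucil	ALKYLATING
Cisplatin	ALKYLATING
Cyclophosphamide	ALKYLATING
Dacarbazine	ALKYLATING
Estramustine	ALKYLATING
Ifosfamide	ALKYLATING
Lomustine	ALKYLATING
Melphalan	ALKYLATING
Nitrogen mustard	ALKYLATING
Oxaliplatin	ALKYLATING
Pipobroman	ALKYLATING
Procarbazine	ALKYLATING
Streptozocin	ALKYLATING
Temozolomide	ALKYLATING
Thiotepa	ALKYLATING
Triethylenemelamine	ALKYLATING
Uramustine	ALKYLATING
Cytochalasin	MICROTUBULE
Docetaxel	MICROTUBULE
Epothilone B	MICROTUBULE
Itraconazole	MICROTUBULE
Ixabepilone	MICROTUBULE
Paclitaxel	MICROTUBULE
Parbendazole	MICROTUBULE
Vinblastine	MICROTUBULE
Vincristine	MICROTUBULE
Vinorelbine	MICROTUBULE
5FU	ANTIMETABOLITE
6-Mercaptopurine	ANTIMETABOLITE
Cladribine	ANTIMETABOLITE
Clofarabine	ANTIMETABOLITE
Cytarabine	ANTIMETABOLITE
Decitabine	ANTIMETABOLITE
Floxuridine	ANTIMETABOLITE
Fludarabine	ANTIMETABOLITE
Fluorouracil	ANTIMETABOLITE
Gemcitabine	ANTIMETABOLITE
Methotrexate	ANTIMETABOLITE
Actinomycin D	ANTITUMOR_ANTIBIOTIC
Bleomycin	ANTITUMOR_ANTIBIOTIC
Daunorubicin	ANTITUMOR_ANTIBIOTIC
Doxorubicin	ANTITUMOR_ANTIBIOTIC
Epirubicin	ANTITUMOR_ANTIBIOTIC
Idarubicin	ANTITUMOR_ANTIBIOTIC
Mitomycin	ANTITUMOR_ANTIBIOTIC
Mitoxantrone	ANTITUMOR_ANTIBIOTIC
Valrubicin	ANTITUMOR_ANTIBIOTIC
Camptothecin	TOPOISOMERASE
Etoposide	TOPOISOMERASE
Irinotecan	TOPOISOMERASE
SN-38	TOPOISOMERASE
Teniposide	TOPOISOMERASE
Topotecan	TOPOISOMERASE
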