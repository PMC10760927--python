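# Eligible ICD-O-3 histology (morphology/behaviour) codes for pancreatic
# carcinoma registry-derived staging. Vocabulary version 1.0.
# Neuroendocrine tumour morphologies are deliberately absent: eligibility is
# a whitelist, so anything not listed (all NETs included) is ineligible.
# code<TAB>description
8000/3	Malignant neoplasm, NOS
8010/3	Carcinoma, NOS
8020/3	Undifferentiated carcinoma
8035/3	Undifferentiated carcinoma with osteoclast-like giant cells
8140/3	Adenocarcinoma, NOS
8441/3	Serous cystadenocarcinoma
8453/3	Intraductal papillary mucinous neoplasm with associated invasive carcinoma
8470/3	Mucinous cystic neoplasm with associated invasive carcinoma
8480/3	Mucinous carcinoma
8481/3	Mucin-producing adenocarcinoma
8490/3	Signet ring cell carcinoma
8500/3	Ductal adenocarcinoma
8503/3	Intraductal tubulopapillary neoplasm with associated invasive carcinoma
8510/3	Medullary carcinoma
8550/3	Acinar cell carcinoma
8551/3	Acinar cell cystadenocarcinoma
8552/3	Mixed acinar-ductal carcinoma
8560/3	Adenosquamous carcinoma
8576/3	Hepatoid carcinoma
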