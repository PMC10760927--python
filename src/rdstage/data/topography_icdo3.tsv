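# Pancreatic ICD-O-3 topography codes. Vocabulary version 1.0.
# code<TAB>description
C250	Head of pancreas
C251	Body of pancreas
C252	Tail of pancreas
C253	Pancreatic duct
C257	Other specified parts of pancreas
C258	Overlapping lesion of pancreas
C259	Pancreas, NOS
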