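canonical_specific	general	base_class	interdisciplinary_flag	synonyms
Genetics	Biological Sciences	domain	0	Genomics;Genetics and Genomics
Molecular Biology	Biological Sciences	domain	0	Molecular and Cellular Biology;Cell Biology
Biochemistry	Biological Sciences	domain	0	Biochemistry and Molecular Biology
Microbiology	Biological Sciences	domain	0
Biology	Biological Sciences	domain	0	Biological Sciences;Life Sciences
Ecology	Biological Sciences	domain	0	Ecology and Evolutionary Biology;Evolutionary Biology
Plant Sciences	Biological Sciences	domain	0	Botany;Plant Biology
Neuroscience	Biological Sciences	domain	0	Neurobiology
Medicine	Health Sciences	domain	0	Medical Sciences;Clinical Medicine
Public Health	Health Sciences	domain	0	Epidemiology
Pathology	Health Sciences	domain	0
Oncology	Health Sciences	domain	0	Cancer Research
Computer Science	Computer Sciences	development	0	Computer Sciences;Computing;Informatics;Computer Science and Engineering
Mathematics	Mathematics and Statistics	development	0	Applied Mathematics
Statistics	Mathematics and Statistics	development	0
Engineering	Engineering	development	0	Electrical Engineering;Mechanical Engineering;Chemical Engineering
Physics	Physical Sciences	development	0	Physical Sciences
Chemistry	Physical Sciences	development	0
Bioinformatics	Biological Sciences	domain	1	Computational Biology;Bioinformatics and Computational Biology;Systems Biology
Biostatistics	Mathematics and Statistics	development	1
Biomathematics	Mathematics and Statistics	development	1	Mathematical Biology
Biophysics	Biological Sciences	domain	1
Biomedical Engineering	Engineering	development	1	Bioengineering
Medical Informatics	Technologies	development	1	Biomedical Informatics;Health Informatics;Clinical Informatics
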