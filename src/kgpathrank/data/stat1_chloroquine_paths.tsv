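# Published top-ranked path records for the STAT1 -> chloroquine case study.
# Columns: declared_depth<TAB>path_record<TAB>score
# One depth-3-labeled row has four edges (printed as-is in the source table).
2	stat1--co_occur--weight loss--co_occur--chloroquine	0.700930
2	stat1--co_occur--mice--co_occur--chloroquine	0.593730
2	stat1--co_occur--mnv--co_occur--chloroquine	0.559861
3	stat1--gene_gene--oasl--co_occur--eif2ak2--co_occur--chloroquine	1.402100
3	stat1--gene_gene--oasl--co_occur--eif2ak2--co_occur--chloroquine	1.402100
3	stat1--gene_gene--oas2--co_occur--oas1--co_occur--chloroquine	1.347831
3	stat1--gene_gene--oas2--co_occur--oas1--co_occur--chloroquine	1.347831
3	stat1--gene_gene--mx2--co_occur--eif2ak2--co_occur--chloroquine	1.345132
3	stat1--co_occur--mx2--co_occur--eif2ak2--co_occur--chloroquine	1.345132
3	stat1--gene_gene--mx2--co_occur--eif2ak2--co_occur--chloroquine	1.345132
3	stat1--gene_gene--mx2--gene_gene--eif2ak2--co_occur--chloroquine	1.345132
3	stat1--co_occur--mx2--gene_gene--eif2ak2--co_occur--chloroquine	1.345132
3	stat1--gene_gene--mx2--gene_gene--eif2ak2--co_occur--chloroquine	1.345132
3	stat1--co_occur--isg15--gene_gene--eif2ak2--co_occur--chloroquine	1.267028
3	stat1--gene_gene--isg15--gene_gene--eif2ak2--co_occur--chloroquine	1.267028
3	stat1--gene_gene--isg15--gene_gene--eif2ak2--co_occur--chloroquine	1.267028
3	stat1--co_occur--mx1--gene_gene--oas1--co_occur--chloroquine	1.248431
3	stat1--gene_gene--mx1--gene_gene--oas1--co_occur--chloroquine	1.248431
3	stat1--co_occur--mx1--co_occur--oas1--co_occur--chloroquine	1.248431
3	stat1--gene_gene--mx1--co_occur--oas1--co_occur--chloroquine	1.248431
3	stat1--gene_gene--mx1--co_occur--oas1--co_occur--chloroquine	1.248431
3	stat1--gene_gene--mx1--gene_gene--oas1--co_occur--chloroquine	1.248431
3	stat1--co_occur--jak1--co_occur--eif2ak2--co_occur--chloroquine	1.242361
3	stat1--gene_gene--jak1--gene_gene--eif2ak2--co_occur--chloroquine	1.242361
3	stat1--gene_gene--jak1--co_occur--eif2ak2--co_occur--chloroquine	1.242361
3	stat1--co_occur--jak1--gene_gene--eif2ak2--co_occur--chloroquine	1.242361
3	stat1--gene_gene--jak1--co_occur--eif2ak2--co_occur--chloroquine	1.242361
3	stat1--gene_gene--jak1--gene_gene--eif2ak2--co_occur--chloroquine	1.242361
3	stat1--gene_gene--mx1--gene_gene--eif2ak2--co_occur--chloroquine	1.233766
3	stat1--co_occur--mx1--co_occur--eif2ak2--co_occur--chloroquine	1.233766
3	stat1--gene_gene--mx1--co_occur--eif2ak2--co_occur--chloroquine	1.233766
3	stat1--gene_gene--mx1--gene_gene--eif2ak2--co_occur--chloroquine	1.233766
3	stat1--co_occur--mx1--gene_gene--eif2ak2--co_occur--chloroquine	1.233766
3	stat1--gene_gene--mx1--co_occur--eif2ak2--co_occur--chloroquine	1.233766
3	stat1--gene_disease--jc virus infection--co_occur--myalgia--co_occur--arthralgia--co_occur--chloroquine	1.402100
4	stat1--gene_disease--jc virus infection--co_occur--dengue shock syndrome--co_occur--arthralgia--co_occur--chloroquine	1.015049
4	stat1--gene_disease--jc virus infection--co_occur--oas2--co_occur--oas1--co_occur--chloroquine	0.973442
4	stat1--gene_disease--jc virus infection--co_occur--hyperglycemia--co_occur--metformin--co_occur--chloroquine	0.966955
4	stat1--gene_disease--jc virus infection--co_occur--mx2--gene_gene--eif2ak2--co_occur--chloroquine	0.906810
4	stat1--gene_disease--jc virus infection--co_occur--mx2--co_occur--eif2ak2--co_occur--chloroquine	0.878100
4	stat1--gene_disease--jc virus infection--co_occur--phenazopyridine--co_occur--monensin sodium--co_occur--chloroquine	0.878100
4	stat1--gene_disease--jc virus infection--co_occur--alphavirus infections--co_occur--arthralgia--co_occur--chloroquine	0.876126
4	stat1--gene_disease--jc virus infection--co_occur--a226v--co_occur--arthralgia--co_occur--chloroquine	0.793003
4	stat1--gene_disease--jc virus infection--co_occur--empyema--co_occur--pneumonia--co_occur--chloroquine	0.787724
4	stat1--gene_disease--jc virus infection--co_occur--pleural effusion--co_occur--pneumonia--co_occur--chloroquine	0.777438
4	stat1--gene_disease--jc virus infection--co_occur--pneumococcal pneumonia--co_occur--pneumonia--co_occur--chloroquine	0.739655
4	stat1--gene_disease--jc virus infection--co_occur--ly96--gene_gene--eif2ak2--co_occur--chloroquine	0.736294
4	stat1--gene_disease--jc virus infection--co_occur--usp18--gene_gene--eif2ak2--co_occur--chloroquine	0.710234
4	stat1--gene_disease--jc virus infection--co_occur--hypoxia--co_occur--arthralgia--co_occur--chloroquine	0.708574
4	stat1--gene_disease--jc virus infection--co_occur--isg15--gene_gene--eif2ak2--co_occur--chloroquine	0.707835
4	stat1--gene_disease--jc virus infection--co_occur--bronchiectasis--co_occur--bronchiolitis--co_occur--chloroquine	0.702962
4	stat1--gene_disease--jc virus infection--co_occur--asthma--co_occur--bronchiolitis--co_occur--chloroquine	0.697532
4	stat1--gene_disease--jc virus infection--co_occur--dhf--co_occur--arthralgia--co_occur--chloroquine	0.694675
4	stat1--gene_disease--jc virus infection--co_occur--socs1--co_occur--eif2ak2--co_occur--chloroquine	0.692914
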