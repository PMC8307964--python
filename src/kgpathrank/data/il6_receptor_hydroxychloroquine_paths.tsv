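# Published top-ranked path records for the IL-6 receptor -> hydroxychloroquine case study.
# Columns: declared_depth<TAB>path_record<TAB>score
2	Il-6_receptor--co_occur--ebola virus--co_occur--hydroxychloroquine	0.271000
3	il-6 receptor--co_occur--ebola virus--co_occur--chloroquine--co_occur--hydroxychloroquine	0.983559
3	il-6 receptor--co_occur--ebola virus--co_occur--quinoline--co_occur--hydroxychloroquine	0.967936
3	il-6 receptor--co_occur--ebola virus--co_occur--amodiaquine--co_occur--hydroxychloroquine	0.964461
3	il-6 receptor--co_occur--cd4--co_occur--chloroquine--co_occur--hydroxychloroquine	0.902787
3	il-6 receptor--co_occur--il17a--gene_disease--rheumatoid arthritis--co_occur--hydroxychloroquine	0.895744
3	il-6 receptor--co_occur--il17a--gene_disease--autoimmune diseases--co_occur--hydroxychloroquine	0.887945
3	il-6 receptor--co_occur--il10--gene_disease--autoimmune diseases--co_occur--hydroxychloroquine	0.884826
3	il-6 receptor--co_occur--il10--co_occur--autoimmune diseases--co_occur--hydroxychloroquine	0.884826
3	il-6 receptor--co_occur--cd83--gene_disease--autoimmune diseases--co_occur--hydroxychloroquine	0.882492
3	il-6 receptor--co_occur--ccr7--gene_disease--autoimmune diseases--co_occur--hydroxychloroquine	0.860170
4	il-6 receptor--co_occur--cd83--gene_gene--cd86--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.275014
4	il-6 receptor--co_occur--ccr2--gene_gene--ccr1--gene_disease--malaria--co_occur--hydroxychloroquine	1.262865
4	il-6 receptor--co_occur--ccr2--gene_gene--ccr3--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.247009
4	il-6 receptor--co_occur--ccr2--co_occur--cx3cr1--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.229658
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcr3--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.225782
4	il-6 receptor--co_occur--ccr2--gene_gene--ccr5--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.214904
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcr5--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.198998
4	il-6 receptor--co_occur--ccr2--gene_gene--ccr6--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.185817
4	il-6 receptor--co_occur--gsto1--gene_gene--prdx2--gene_disease--malaria--co_occur--hydroxychloroquine	1.177270
4	il-6 receptor--co_occur--ccr2--gene_gene--ccr3--gene_disease--malaria--co_occur--hydroxychloroquine	1.169309
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcr3--gene_disease--malaria--co_occur--hydroxychloroquine	1.151890
4	il-6 receptor--co_occur--ccr2--gene_gene--ccl7--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.149486
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcr1--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.149216
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcl10--gene_disease--malaria--co_occur--hydroxychloroquine	1.144627
4	il-6 receptor--co_occur--ccr2--gene_gene--ccl22--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.138721
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcr2--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.136466
4	il-6 receptor--co_occur--ccr2--gene_gene--ccr7--gene_disease--malaria--co_occur--hydroxychloroquine	1.126956
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcl8--gene_disease--malaria--co_occur--hydroxychloroquine	1.123747
4	il-6 receptor--co_occur--ccr2--gene_gene--ccl20--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.119462
4	il-6 receptor--co_occur--ccr2--co_occur--ccl2--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.119136
4	il-6 receptor--co_occur--ccr2--gene_gene--ccl2--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.119136
4	il-6 receptor--co_occur--gsto1--gene_gene--gstk1--gene_disease--malaria--co_occur--hydroxychloroquine	1.119127
4	il-6 receptor--co_occur--ccr2--gene_gene--ccl22--gene_disease--malaria--co_occur--hydroxychloroquine	1.117001
4	il-6 receptor--co_occur--ccr2--gene_gene--ccl2--gene_disease--malaria--co_occur--hydroxychloroquine	1.116415
4	il-6 receptor--co_occur--ccr2--co_occur--ccl2--gene_disease--malaria--co_occur--hydroxychloroquine	1.116415
4	il-6 receptor--co_occur--ccr2--gene_gene--cx3cl1--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.092402
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcl12--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.092225
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcl10--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.086009
4	il-6 receptor--co_occur--ccr2--gene_gene--cxcr6--gene_disease--hiv infections--co_occur--hydroxychloroquine	1.081086
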