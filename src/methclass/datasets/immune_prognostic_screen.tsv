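gene	logrank_p	logrank_padj_published	hazard_ratio	hpa_p	hpa_padj_published
CCR5	0.0268	0.0804	0.3279	0.00194	0.00418
CXCL9	0.0892	0.0931	0.4483	0.00686	0.0087
CXCR3	0.0806	0.0912	0.4847	0.00305	0.0048
IL10RA	0.0705	0.0912	0.4541	0.002	0.0042
IL18RAP	0.0102	0.0612	0.3637	0.00627	0.0084
ITGAX	0.063	0.0912	0.4837	0.0249	0.0249
CCR2	0.0549	0.0912	0.3987	0.000628	0.0023
DOCK2	0.078	0.0912	0.486	0.0184	0.0201
WAS	0.0836	0.0912	0.5171	0.00209	0.0042
BTK	0.0949	0.0949	0.4938	0.00251	0.0046
CD3D	0.0648	0.0912	0.4393	0.0000846	0.0016
CD3E	0.009	0.0612	0.3262	0.000162	0.0016
CD7	0.0361	0.0912	0.4499	0.000551	0.0023
CD48	0.046	0.0912	0.4262	0.0017	0.0042
CD247	0.0654	0.0912	0.5043	0.00321	0.0048
CTLA4	0.0696	0.0912	0.4556	0.00913	0.011
GZMB	0.0664	0.0912	0.4189	0.0028	0.0048
ITGAL	0.0216	0.0804	0.3823	0.00426	0.006
ITK	0.0253	0.0804	0.4266	0.000657	0.0023
KLRK1	0.00449	0.05388	0.3	0.000265	0.0016
PIK3CG	0.0819	0.0912	0.46	0.0201	0.021
PTPRC	0.0175	0.0804	0.3662	0.0124	0.0142
SELL	0.000698	0.0168	0.2366	0.000225	0.0016
SPN	0.0508	0.0912	0.4424	0.00163	0.0042
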