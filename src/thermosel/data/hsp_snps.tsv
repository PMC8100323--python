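snp_id	ed	mutation	location	gene_id
4949-1	0.7267	C/A	Intron	CGI_10004949
22585-2	0.7189	A/T	Upstream	CGI_10022585
22585-1	0.6809	C/T	Upstream	CGI_10022585
4949-2	0.6678	A/G	Intron	CGI_10004949
4823	0.697	A/C	Downstream	CGI_10004823
24709	0.6835	A/T	Intron	CGI_10024709
12734	0.6727	C/T	Downstream	CGI_10012734
13528	0.6613	A/T	Intron	CGI_10013528
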