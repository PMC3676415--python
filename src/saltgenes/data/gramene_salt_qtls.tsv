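qtl_id	chrom	start	end
AQEM001	1	33956950	37713775
AQEM006	1	9820009	11232822
AQEM008	1	33956950	37713775
AQGR001	1	38530957	38531467
AQGR002	3	22798284	22830744
AQCL001	3	484860	485333
AQCL002	4	33663984	33664487
AQEM009	4	19928370	22355854
AQCL003	5	18874932	18875558
AQEM002	6	21605889	24919236
AQCL004	6	22862400	22862821
AQEM003	7	4573316	7739951
AQEM004	7	2633784	4575215
AQEM010	7	2633784	4575215
AQEM005	7	2633784	4575215
AQEM011	7	2633784	4575215
AQEM007	9	14362062	17837010
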