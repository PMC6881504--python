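# Published ChIP-qPCR validation loci for the rice butyrylation mark:
# 12 peak sites and 12 non-peak sites, one per chromosome.
# Raw Ct columns are reconstructed from the printed delta-Ct (qPCR2)
# values using a nominal 25-cycle input baseline, so qPCR2 = ct_input - ct_chip
# reproduces the printed values exactly.
site_id	class	ct_input	ct_chip
LOC_Os01g02960	peak	25.000000	23.767510
LOC_Os02g10180	peak	25.000000	23.525000
LOC_Os03g06210	peak	25.000000	23.192784
LOC_Os04g37580	peak	25.000000	23.947095
LOC_Os05g04950	peak	25.000000	23.969996
LOC_Os06g06410	peak	25.000000	24.206000
LOC_Os07g17220	peak	25.000000	24.431115
LOC_Os08g08205	peak	25.000000	23.343271
LOC_Os09g28310	peak	25.000000	23.343271
LOC_Os10g28254	peak	25.000000	24.617041
LOC_Os11g26130	peak	25.000000	24.598296
LOC_Os12g43750	peak	25.000000	23.815982
LOC_Os01g01320	non_peak	25.000000	26.340710
LOC_Os02g38870	non_peak	25.000000	25.142400
LOC_Os03g02650	non_peak	25.000000	24.580547
LOC_Os04g02030	non_peak	25.000000	25.324650
LOC_Os05g25510	non_peak	25.000000	25.576540
LOC_Os06g02930	non_peak	25.000000	23.038263
LOC_Os07g37370	non_peak	25.000000	24.260535
LOC_Os08g23640	non_peak	25.000000	25.093660
LOC_Os09g39170	non_peak	25.000000	23.391156
LOC_Os10g01590	non_peak	25.000000	25.976790
LOC_Os11g02810	non_peak	25.000000	24.133231
LOC_Os12g43220	non_peak	25.000000	25.687911
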