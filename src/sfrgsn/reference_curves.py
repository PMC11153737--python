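"""Published F1/CBR reference curves for the LUAD and BRCA runs.

These are the cross-validated F1 scores (percent) and cost-benefit ratios
reported for the lung-adenocarcinoma and breast-carcinoma stage and subtype
classifications at feature-count thresholds 1..10. They serve as worked
examples and as fixed inputs for validating the CBR arithmetic and the
first-below-0.5 stopping rule: differencing consecutive F1 entries must
reproduce the printed CBR cells, and the stopping rule must return 7 (LUAD
stages), 5 (BRCA stages), 5 (LUAD subtypes) and 6 (BRCA subtypes).

Note: the LUAD subtype CBR cells at k = 3..7 are not consistent with
differencing their own F1 column (the column appears partially shifted in
the source); ``LUAD_SUBTYPE_CBR_CONSISTENT`` lists the ks that are.
"""

LUAD_STAGE_F1 = {1: 48.7420, 2: 86.2510, 3: 91.2557, 4: 92.5050, 5: 93.3089,
                 6: 96.1537, 7: 96.8517, 8: 96.9067, 9: 97.4935, 10: 97.8804}
LUAD_STAGE_CBR = {2: 37.5090, 3: 5.0047, 4: 1.2492, 5: 0.8039, 6: 2.8448,
                  7: 0.6979, 8: 0.0550, 9: 0.5868, 10: 0.3868}

BRCA_STAGE_F1 = {1: 71.9124, 2: 93.4443, 3: 95.3618, 4: 96.2117, 5: 97.2808,
                 6: 97.4655, 7: 98.2629, 8: 99.1047, 9: 98.3727, 10: 99.0001}
BRCA_STAGE_CBR = {2: 21.5318, 3: 1.9174, 4: 0.8499, 5: 1.0691, 6: 0.1846,
                  7: 0.7974, 8: 0.8417, 9: -0.7319, 10: 0.6273}

LUAD_SUBTYPE_F1 = {1: 73.2800, 2: 91.3155, 3: 95.9758, 4: 96.8973, 5: 97.3499,
                   6: 97.7847, 7: 97.7847, 8: 97.7847, 9: 97.7847, 10: 98.2410}
LUAD_SUBTYPE_CBR = {2: 18.0354, 3: 4.1303, 4: 0.5300, 5: 0.9214, 6: 0.4526,
                    7: 0.4347, 8: 0.0, 9: 0.0, 10: 0.4563}
LUAD_SUBTYPE_CBR_CONSISTENT = (2, 8, 9, 10)

BRCA_SUBTYPE_F1 = {1: 51.2668, 2: 81.9457, 3: 89.6415, 4: 93.2176, 5: 94.4989,
                   6: 96.4546, 7: 96.9095, 8: 97.3826, 9: 97.3919, 10: 97.7572}
BRCA_SUBTYPE_CBR = {2: 30.6788, 3: 7.6958, 4: 3.5760, 5: 1.2813, 6: 1.9557,
                    7: 0.4549, 8: 0.4731, 9: 0.0093, 10: 0.3652}

# optimal feature counts reported for each run under the 0.5 stopping rule
OPTIMAL_K = {"luad_stage": 7, "brca_stage": 5,
             "luad_subtype": 5, "brca_subtype": 6}

# F1 (percent) at the selected count, as reported alongside the tables
F1_AT_OPTIMAL = {"luad_stage": 96.8517, "brca_stage": 97.2808}
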