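metric,subject,lungs_manual,lungs_auto,heart_manual,heart_auto,liver_manual,liver_auto,stomach_manual,stomach_auto
similarity,1,0.91,0.91,0.89,0.88,,,,
similarity,2,0.92,0.90,0.91,0.92,0.89,0.90,0.84,0.83
similarity,3,0.91,0.91,0.93,0.86,0.91,0.91,0.85,0.81
similarity,4,0.94,0.91,0.88,0.87,0.92,0.91,0.85,0.83
similarity,5,0.92,0.91,0.89,0.96,0.93,0.95,0.79,0.83
similarity,6,0.93,0.94,0.92,0.90,0.92,0.93,0.76,0.78
similarity,7,0.93,0.93,0.89,0.89,0.94,0.95,0.90,0.91
similarity,8,0.93,0.94,0.89,0.91,0.87,0.89,0.78,0.75
similarity,9,,,0.87,0.89,0.91,0.91,0.83,0.87
similarity,10,0.92,0.92,0.87,0.84,0.91,0.91,0.83,0.82
similarity,Average,0.92,0.92,0.89,0.89,0.91,0.92,0.82,0.83
similarity,SD,0.02,0.01,0.02,0.04,0.02,0.02,0.04,0.04
sensitivity,1,0.93,0.93,0.93,0.90,,,,
sensitivity,2,0.94,0.94,0.95,0.95,0.93,0.93,0.87,0.85
sensitivity,3,0.93,0.94,0.96,0.96,0.93,0.93,0.91,0.87
sensitivity,4,0.95,0.93,0.91,0.91,0.94,0.92,0.89,0.87
sensitivity,5,0.94,0.93,0.94,0.97,0.94,0.96,0.83,0.85
sensitivity,6,0.94,0.95,0.96,0.91,0.94,0.94,0.81,0.80
sensitivity,7,0.95,0.95,0.92,0.91,0.95,0.96,0.94,0.93
sensitivity,8,0.94,0.95,0.92,0.93,0.90,0.92,0.84,0.80
sensitivity,9,,,0.92,0.92,0.93,0.93,0.88,0.90
sensitivity,10,0.94,0.95,0.91,0.88,0.93,0.94,0.87,0.86
sensitivity,Average,0.94,0.94,0.93,0.92,0.93,0.94,0.87,0.86
sensitivity,SD,0.02,0.01,0.03,0.04,0.01,0.01,0.04,0.04
specificity,1,0.98,0.97,0.95,0.97,,,,
specificity,2,0.94,0.94,0.98,0.97,0.93,0.93,0.96,0.97
specificity,3,0.93,0.94,0.96,0.90,0.93,0.93,0.93,0.93
specificity,4,0.98,0.98,0.97,0.96,0.98,0.98,0.95,0.94
specificity,5,0.97,0.98,0.95,0.98,0.98,0.99,0.94,0.97
specificity,6,0.99,0.98,0.96,0.99,0.98,0.98,0.93,0.97
specificity,7,0.98,0.98,0.96,0.97,0.99,0.99,0.96,0.98
specificity,8,0.98,0.97,0.97,0.98,0.97,0.96,0.91,0.93
specificity,9,,,0.95,0.96,0.97,0.98,0.93,0.97
specificity,10,0.98,0.97,0.95,0.96,0.97,0.97,0.94,0.95
specificity,Average,0.98,0.97,0.96,0.96,0.97,0.97,0.94,0.96
specificity,SD,0.03,0.02,0.03,0.04,0.02,0.02,0.02,0.02
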