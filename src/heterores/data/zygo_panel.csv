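# Sorbic acid resistance parameters for the main Zygosaccharomyces panel
# (29 food-spoilage isolates; per-strain means over biological replicates).
# heteroresistance: SD of log10(single-cell resistance); ic50_mM: population
# median (mM); mic_model_mM: 99.99th percentile of the fitted distribution.
strain_id,species,heteroresistance,ic50_mM,mic_model_mM
1730,Z. pseudobailii,0.0648,3.77,6.69
3697,Z. pseudobailii,0.0899,3.16,7.00
3698,Z. parabailii,0.0726,2.41,4.57
3699,Z. parabailii,0.0453,3.59,5.36
3704,Z. parabailii,0.0436,4.40,6.47
3942,Z. parabailii,0.0828,3.40,7.07
3959,Z. parabailii,0.1054,3.56,9.04
7406,Z. parabailii,0.0688,4.06,7.46
7445,Z. parabailii,0.0689,3.58,6.58
7768,Z. bailii,0.0673,5.06,9.18
7769,Z. pseudobailii,0.0760,3.63,7.11
7777,Z. parabailii,0.0456,4.08,6.11
7788,Z. bailii,0.0502,4.11,6.40
7800,Z. bailii,0.0635,2.71,4.76
7807,Z. parabailii,0.0538,3.76,6.05
7809,Z. pseudobailii,0.0857,2.32,4.95
7812,Z. parabailii,0.0458,4.09,6.13
7820,Z. pseudobailii,0.0719,3.05,5.77
7829,Z. parabailii,0.0897,3.37,7.46
7836,Z. pseudobailii,0.0643,3.28,5.80
7838,Z. parabailii,0.0345,4.35,5.91
7842,Z. parabailii,0.0520,4.93,7.82
7843,Z. bailii,0.0653,2.92,5.20
7851,Z. pseudobailii,0.0935,3.01,6.88
7852,Z. bailii,0.0380,3.06,4.28
7862,Z. parabailii,0.0537,3.79,6.09
7870,Z. parabailii,0.0453,5.38,8.03
7871,Z. parabailii,0.0647,4.22,7.49
7873,Z. parabailii,0.0637,3.52,6.19
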