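"""Published four-sea r.n.a. rows used as fixed worked examples.

Each row: gene cluster id -> (r.n.a. over RS, MED, BATS, HOT; reported
entropy in nats; total mapped reads).  The r.n.a. values are printed to three
decimals, so recomputed entropies are compared within +/-0.005 and row sums
within +/-0.001.
"""

REFERENCE_ROWS = {
    # Prochlorococcus gene clusters
    "PRO2654": ((0.540, 0.000, 0.197, 0.263), 1.004, 108),
    "PRO2267": ((0.488, 0.032, 0.118, 0.362), 1.081, 111),
    "PRO2760": ((0.397, 0.037, 0.289, 0.277), 1.204, 368),
    "PRO2575": ((0.465, 0.102, 0.167, 0.265), 1.240, 93),
    "PRO2420": ((0.445, 0.077, 0.246, 0.231), 1.242, 122),
    "PRO2498": ((0.363, 0.057, 0.309, 0.271), 1.248, 119),
    "PRO1012": ((0.423, 0.115, 0.142, 0.320), 1.254, 116),
    "PRO2504": ((0.405, 0.072, 0.246, 0.277), 1.257, 138),
    "PRO2832": ((0.063, 0.462, 0.466, 0.009), 0.929, 121),
    "PRO2983": ((0.055, 0.449, 0.480, 0.016), 0.937, 325),
    "PRO2362": ((0.075, 0.637, 0.164, 0.124), 1.037, 97),
    "PRO2369": ((0.101, 0.555, 0.267, 0.077), 1.110, 94),
    "PRO2623": ((0.198, 0.342, 0.433, 0.026), 1.146, 188),
    "PRO2683": ((0.203, 0.388, 0.346, 0.063), 1.232, 218),
    "PRO3097": ((0.195, 0.470, 0.132, 0.203), 1.264, 117),
    "PRO2524": ((0.287, 0.000, 0.406, 0.308), 1.087, 119),
    "PRO2684": ((0.215, 0.200, 0.515, 0.070), 1.181, 122),
    "PRO2216": ((0.313, 0.064, 0.347, 0.276), 1.262, 163),
    "PRO1312": ((0.310, 0.043, 0.319, 0.328), 1.228, 258),
    "PRO2365": ((0.308, 0.048, 0.314, 0.330), 1.239, 151),
    # cyanophage gene clusters
    "PH1590": ((0.551, 0.034, 0.076, 0.340), 1.004, 100),
    "PH1063": ((0.526, 0.282, 0.000, 0.192), 1.012, 40),
    "PH1210": ((0.599, 0.056, 0.255, 0.090), 1.034, 75),
    "PH1309": ((0.435, 0.328, 0.000, 0.236), 1.069, 114),
    "PH1105": ((0.000, 1.000, 0.000, 0.000), 0.000, 40),
    "PH1135": ((0.000, 1.000, 0.000, 0.000), 0.000, 54),
    "PH1180": ((0.000, 0.968, 0.000, 0.032), 0.142, 38),
    "PH1046": ((0.095, 0.519, 0.000, 0.386), 0.931, 52),
    "PH1144": ((0.192, 0.469, 0.000, 0.339), 1.039, 42),
    "PH1009": ((0.365, 0.445, 0.000, 0.190), 1.043, 46),
    "PH1168": ((0.016, 0.359, 0.607, 0.018), 0.807, 37),
    "PH1434": ((0.000, 0.310, 0.515, 0.175), 1.010, 44),
    "PH1133": ((0.068, 0.259, 0.577, 0.096), 1.076, 223),
    "PH1145": ((0.241, 0.084, 0.000, 0.675), 0.816, 40),
    "PH1574": ((0.393, 0.047, 0.000, 0.560), 0.835, 37),
    "PH1376": ((0.000, 0.096, 0.290, 0.614), 0.884, 37),
    "PH1606": ((0.387, 0.148, 0.000, 0.465), 1.006, 169),
    "PH1158": ((0.309, 0.212, 0.000, 0.479), 1.044, 38),
    "PH1033": ((0.244, 0.337, 0.000, 0.419), 1.075, 103),
}

#: the six rows used as individual worked examples
WORKED_EXAMPLES = ["PRO2654", "PH1105", "PH1180", "PRO2832", "PH1046", "PRO2267"]
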