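"""Physical constants (SI, CODATA 2018 exact values where defined)."""

FARADAY = 96485.33212331001  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # 1/mol
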