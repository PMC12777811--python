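"""Internal unit conventions.

Everything inside the package works in: time h, concentration ng/ml,
volume ml, dose mg, clearance l/h, volume-of-distribution l.  The two
constants below are the only conversion factors, applied at module
boundaries (dose into amounts, clearance out of ml/h).
"""

NG_PER_MG = 1.0e6
ML_PER_L = 1000.0
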