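"""Canonical unit system: micrometre, second, millipascal-second.

In these units hydraulic resistance is mPa·s/µm³, compliance is µm³/mPa and
an R·C product is directly a time in seconds, which keeps compliance values
on the scale at which they are usually reported for microfluidic systems.
Pump flow rates are entered in mL/h and converted on ingestion.
"""

#: µm³/s per mL/h (1 mL = 1e12 µm³, 1 h = 3600 s)
ML_PER_H_TO_UM3_PER_S: float = 1e12 / 3600.0

#: mm expressed in µm (tubing lengths are quoted in mm)
MM_TO_UM: float = 1e3


def ml_per_h_to_um3_per_s(q_ml_h: float) -> float:
    """Convert a flow rate from mL/h to µm³/s."""
    return q_ml_h * ML_PER_H_TO_UM3_PER_S
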