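"""Published summary constants used as analysis inputs.

The photon reference experiment is external to any single ion study: its
ED50 values (single and split dose), the BED50 and the alpha/beta ratio
enter the RBE chain as constants with standard errors rather than being
refit from raw data.  The measured ion-beam summary values (per-LET ED50,
BED50, alpha/beta) are likewise shipped so that ratio identities and
model comparisons can be recomputed without raw animal tables.

All doses in Gy, LET in keV/um, confidence limits at the 90% level.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SummaryValue:
    """A published point estimate with standard error and 90% CL."""

    value: float
    se: float
    cl90: tuple[float, float] | None = None


#: Photon reference: ED50 by fraction number, BED50 and alpha/beta.
PHOTON_ED50 = {
    1: SummaryValue(24.5, 0.8, (23.3, 26.7)),
    2: SummaryValue(34.3, 0.7, (32.9, 36.6)),
}
PHOTON_BED50 = SummaryValue(244.9, 24.3, (208.2, 293.3))
PHOTON_ALPHA_BETA = SummaryValue(2.8, 0.4, (2.2, 3.5))

#: Dose-averaged LET (keV/um) of the four cord positions and their depths (mm).
LET_POSITIONS = (26.0, 66.0, 98.0, 141.0)
DEPTH_BY_LET = {26.0: 35.0, 66.0: 100.0, 98.0: 120.0, 141.0: 127.0}

#: Measured ion ED50 per (LET, n_fractions).
ION_ED50 = {
    (26.0, 1): SummaryValue(17.2, 0.3, (16.5, 17.9)),
    (66.0, 1): SummaryValue(14.4, 0.3, (13.7, 15.0)),
    (98.0, 1): SummaryValue(13.5, 0.4, (12.7, 14.4)),
    (141.0, 1): SummaryValue(15.8, 0.4, (14.9, 16.6)),
    (26.0, 2): SummaryValue(21.7, 0.4, (20.9, 22.4)),
    (66.0, 2): SummaryValue(17.0, 0.5, None),
    (98.0, 2): SummaryValue(15.5, 0.5, None),
    (141.0, 2): SummaryValue(17.2, 0.4, (16.4, 17.9)),
}

#: Measured ion RBE per (LET, n_fractions).
ION_RBE = {
    (26.0, 1): SummaryValue(1.43, 0.05, (1.34, 1.51)),
    (66.0, 1): SummaryValue(1.71, 0.06, (1.60, 1.81)),
    (98.0, 1): SummaryValue(1.82, 0.08, (1.69, 1.96)),
    (141.0, 1): SummaryValue(1.56, 0.06, (1.45, 1.67)),
    (26.0, 2): SummaryValue(1.58, 0.04, (1.51, 1.65)),
    (66.0, 2): SummaryValue(2.01, 0.07, (1.90, 2.13)),
    (98.0, 2): SummaryValue(2.21, 0.08, (2.08, 2.35)),
    (141.0, 2): SummaryValue(1.99, 0.06, (1.90, 2.09)),
}

#: Jointly fitted ion BED50 and alpha/beta per LET (both schedules pooled).
ION_BED50 = {
    26.0: SummaryValue(39.3, 6.8, (30.7, 59.8)),
    66.0: SummaryValue(23.4, 2.1, (20.3, 29.1)),
    98.0: SummaryValue(19.7, 2.1, (16.7, 25.1)),
    141.0: SummaryValue(18.9, 1.5, (16.8, 22.4)),
}
ION_ALPHA_BETA = {
    26.0: SummaryValue(13.4, 4.6, (6.6, 23.8)),
    66.0: SummaryValue(23.0, 6.2, (13.2, 38.9)),
    98.0: SummaryValue(29.5, 12.1, (14.4, 69.5)),
    141.0: SummaryValue(81.2, 47.4, (34.1, 469.9)),
}

#: Maximum RBE (zero fractional-dose limit) per LET.
ION_RBE_MAX = {
    26.0: SummaryValue(6.23, 1.24, (4.59, 8.96)),
    66.0: SummaryValue(10.45, 1.39, (8.36, 12.99)),
    98.0: SummaryValue(12.44, 1.82, (9.79, 15.89)),
    141.0: SummaryValue(12.94, 1.63, (10.44, 15.86)),
}
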