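"""Imaging-dose bookkeeping.

Dose rates per chamber position are packaged constants measured with an
ionization chamber in a thorax phantom on the physical kV imaging system
(125 kVp); positions 1-3 sit in water-equivalent material, position 4 in
bone-equivalent, positions 5-6 in lung-equivalent. No radiation transport
is simulated: scan dose is simply rate times total mAs, which is what makes
gantry speed (through the projection count) directly proportional to
imaging dose at fixed tube output per frame.
"""

from __future__ import annotations

from .acquisition import AcquisitionProtocol, total_mas

#: Measured dose rates in cGy/mAs by chamber position (1-6).
DOSE_RATES_CGY_PER_MAS = {
    1: ("water", 2.86e-3),
    2: ("water", 3.03e-3),
    3: ("water", 2.84e-3),
    4: ("bone", 5.18e-3),
    5: ("lung", 2.49e-3),
    6: ("lung", 2.30e-3),
}


def chamber_material(position: int) -> str:
    """Tissue-mimicking material at a chamber position."""
    _validate(position)
    return DOSE_RATES_CGY_PER_MAS[position][0]


def dose_rate(position: int) -> float:
    """Measured dose rate (cGy/mAs) at a chamber position 1-6."""
    _validate(position)
    return DOSE_RATES_CGY_PER_MAS[position][1]


def scan_dose(position: int, total_mas_value: float) -> float:
    """Imaging dose (cGy) of a scan: dose rate times cumulative mAs."""
    if total_mas_value < 0:
        raise ValueError("total mAs must be non-negative")
    return dose_rate(position) * total_mas_value


def protocol_dose(position: int, protocol: AcquisitionProtocol) -> float:
    """Imaging dose (cGy) of one protocol at full-scale projection count."""
    return scan_dose(position, total_mas(protocol))


def _validate(position: int) -> None:
    if position not in DOSE_RATES_CGY_PER_MAS:
        raise ValueError(
            f"chamber position must be 1-6, got {position}")
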