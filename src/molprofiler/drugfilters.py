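"""Property-based drug-likeness rules.

Three families: Lipinski's Rule-of-Five with the permissive <=1-violation
cutoff, the Oprea ring-count/rigid-bond (RNG/RGB) boxes, and generic
single-descriptor threshold filters (e.g. FASA- < 0.339).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector


class Direction(str, Enum):
    BELOW_IS_POSITIVE = "below_is_positive"
    ABOVE_IS_POSITIVE = "above_is_positive"


@dataclass(frozen=True)
class ThresholdFilter:
    """A one-property drug-likeness rule: positive iff the descriptor falls
    strictly on the stated side of the cutoff (ties are negative)."""
    descriptor_name: str
    cutoff: float
    direction: Direction = Direction.BELOW_IS_POSITIVE

    def __post_init__(self):
        if self.descriptor_name not in DESCRIPTOR_NAMES:
            raise ValueError(f"unknown descriptor: {self.descriptor_name!r}")


#: The best single-descriptor filter reported for separating drug-like from
#: non-drug-like sets: fractional negatively-charged accessible surface area
#: below 0.339 counts as drug-like.
FASA_MINUS_FILTER = ThresholdFilter("FASA-", 0.339, Direction.BELOW_IS_POSITIVE)


@dataclass(frozen=True)
class Ro5Result:
    violations: int
    druglike: bool


_RO5_REQUIRED = ("MW", "AlogP", "N_HBDL", "N_HBAL")


def rule_of_five(dv: DescriptorVector | dict) -> Ro5Result:
    """Rule-of-Five violation count (MW > 500, AlogP > 5, donors > 5,
    acceptors > 10); at most one violation still counts as drug-like."""
    values = dv.values if isinstance(dv, DescriptorVector) else dv
    for k in _RO5_REQUIRED:
        if k not in values:
            raise KeyError(f"Rule-of-Five needs descriptor {k!r}")
    v = sum([
        values["MW"] > 500,
        values["AlogP"] > 5,
        values["N_HBDL"] > 5,
        values["N_HBAL"] > 10,
    ])
    return Ro5Result(violations=v, druglike=v <= 1)


class OpreaBox(str, Enum):
    DRUGLIKE = "druglike_box"
    NONDRUGLIKE = "nondruglike_box"
    NEITHER = "neither"


def oprea_box(dv: DescriptorVector | dict) -> OpreaBox:
    """Oprea's drug-likeness boxes on ring count RNG and rigid-bond count RGB.

    RNG is the SSSR ring count; RGB is taken as heavy-atom bonds minus
    rotatable bonds.  Non-drug-like box: 0 <= RNG <= 2 and RGB <= 17;
    drug-like box: RNG >= 3 and RGB >= 18; the remainder is 'neither'.
    """
    values = dv.values if isinstance(dv, DescriptorVector) else dv
    rng = values["N_Rings"]
    rgb = values["N_Bonds"] - values["N_rot"]
    if 0 <= rng <= 2 and rgb <= 17:
        return OpreaBox.NONDRUGLIKE
    if rng >= 3 and rgb >= 18:
        return OpreaBox.DRUGLIKE
    return OpreaBox.NEITHER


def apply_threshold(dv: DescriptorVector | dict, f: ThresholdFilter) -> bool:
    """Evaluate a threshold filter; flagged-undefined descriptor values are
    classified negative with a warning."""
    if isinstance(dv, DescriptorVector):
        if dv.is_flagged(f.descriptor_name):
            warnings.warn(
                f"descriptor {f.descriptor_name!r} flagged undefined for "
                f"{dv.name!r}; classified negative", stacklevel=2,
            )
            return False
        value = dv[f.descriptor_name]
    else:
        value = dv[f.descriptor_name]
    if f.direction == Direction.BELOW_IS_POSITIVE:
        return value < f.cutoff
    return value > f.cutoff
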