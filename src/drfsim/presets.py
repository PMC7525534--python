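"""Fitted parameter presets for the two driving styles.

The field shape and scene costs are shared between styles (the driver
and the scene did not change between instructions, only how risk is
translated into action): ``normal`` and ``sport`` differ in risk
threshold, desired speed and acceleration aggressiveness.
"""

from __future__ import annotations

from .controller import DriverParams
from .field import DRFParams
from .kinematics import VehicleSpec
from .scene import CostSchema

__all__ = ["DRF_DEFAULT", "DRIVER_PRESETS", "SCHEMA_DEFAULT", "EGO_SPEC",
           "get_preset"]

#: shared field shape (both styles)
DRF_DEFAULT = DRFParams(p=0.0064, t_la=3.5, m=0.001, c=0.5, k1=0.0, k2=1.3823)

#: shared scene costs
SCHEMA_DEFAULT = CostSchema()

#: ego car: 2.0 m wide, 5 m long sedan
EGO_SPEC = VehicleSpec(width=2.0, length=5.0, wheelbase=2.9)

DRIVER_PRESETS = {
    "normal": DriverParams(c_t=3000.0, v_des=21.6, k_v=0.14, k_vc=1.5e-4),
    "sport": DriverParams(c_t=5200.0, v_des=26.0, k_v=0.30, k_vc=1.5e-4),
}


def get_preset(name: str) -> DriverParams:
    try:
        return DRIVER_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: "
            f"{', '.join(DRIVER_PRESETS)}") from None
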