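"""biegm: forward simulation of bipolar electrograms on atrial tissue models.

Monodomain wave propagation with human atrial membrane kinetics, virtual
bipolar mapping catheters (Thermocool / Pentaray / Orion geometries),
extracellular-potential forward modelling, and the experiment drivers for
orientation / contact-angle / conduction-velocity / scar / fibrillation
studies of electrogram morphology.
"""

from .ionic import (
    CellState,
    IonicParams,
    PacingProtocol,
    calibrate_apd,
    ionic_rhs,
    measure_apd90,
    resting_state,
    simulate_cell,
)

__version__ = "0.1.0"

__all__ = [
    "CellState",
    "IonicParams",
    "PacingProtocol",
    "calibrate_apd",
    "ionic_rhs",
    "measure_apd90",
    "resting_state",
    "simulate_cell",
    "__version__",
]


def __getattr__(name):
    # convenience re-exports without importing the heavy stack eagerly
    lazy = {
        "TissueModel": ("biegm.mesh", "TissueModel"),
        "make_sheet": ("biegm.geometry", "make_sheet"),
        "builtin_designs": ("biegm.catheter", "builtin_designs"),
        "SheetStudy": ("biegm.experiments", "SheetStudy"),
    }
    if name in lazy:
        import importlib

        module, attr = lazy[name]
        return getattr(importlib.import_module(module), attr)
    raise AttributeError(f"module 'biegm' has no attribute {name!r}")
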