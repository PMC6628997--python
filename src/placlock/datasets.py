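"""Packaged coefficient tables.

The files under ``placlock/data`` are *synthetic* stand-ins for the
published placental-clock supplements: they reproduce the documented
structure — the robust placental clock's 558 CpGs, the control clock's
546, their 199-probe overlap, the refined clock's 395 CpGs (a subset of
the robust clock's), and the 220-CpG fetal sex-classifier — with
deterministic pseudo-random probe identities and weights. They exercise
every coefficient-table code path; applying them to real arrays does not
yield gestational ages. Regenerate with
``scripts/make_synthetic_clock_fixtures.py``.
"""

from __future__ import annotations

from importlib import resources

from .io import read_clock
from .types import ClockModel

__all__ = ["packaged_clock_names", "load_packaged_clock"]

_FILES = {
    "RPC": "rpc_synthetic.csv",
    "CPC": "cpc_synthetic.csv",
    "refined_RPC": "refined_rpc_synthetic.csv",
    "sex_classifier": "sex_classifier_synthetic.csv",
}


def packaged_clock_names() -> list[str]:
    return list(_FILES)


def load_packaged_clock(name: str) -> ClockModel:
    """Load one of the packaged synthetic coefficient tables by short name
    (``"RPC"``, ``"CPC"``, ``"refined_RPC"`` or ``"sex_classifier"``)."""
    if name not in _FILES:
        raise KeyError(f"unknown packaged clock {name!r}; "
                       f"choose from {sorted(_FILES)}")
    ref = resources.files("placlock.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return read_clock(path, name=name)
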