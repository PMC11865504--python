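"""Configuration: parameter files, reference conditions, seed fan-out.

Parameter sets are plain dataclasses; YAML configs mirror their fields in
nested sections and unknown keys are rejected so typos fail loudly.  The
two reference conditions used throughout (a bulk gel-layer emulsion and a
fuelled synthetic cell) are constructed here so simulations, tests and the
reproduction scripts all share one source of defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cell_sim import CellParams
from .chem_cycle import KineticParams
from .size_control import FOUR_THIRDS_PI, DropletFieldParams
from .synthetic_data import RenderOpts

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "bulk_reference",
    "cell_reference",
    "child_seeds",
]

#: Aqueous fuel at the bulk (gel-layer) reference condition, mM.  Sits in
#: the middle of the steady-state fuel range the droplet experiments span.
REFERENCE_FUEL_MM = 7.0
#: Total peptide at the bulk reference condition, mM.
REFERENCE_PEPTIDE_MM = 14.0
#: System volume used for mean-field bulk emulsions, µm³.
REFERENCE_VOLUME_UM3 = 1.0e5


def bulk_reference(**chem_overrides) -> tuple[DropletFieldParams, float, float]:
    """Gel-layer bulk emulsion reference: (field params, c_total, volume).

    The oil fuel level is set so the aqueous steady fuel is
    ``REFERENCE_FUEL_MM``; nucleation is fast enough to pin the pool near
    c_sat at steady state.
    """
    chem = KineticParams().with_(**chem_overrides)
    chem = chem.with_(c_fuel_oil=REFERENCE_FUEL_MM / chem.K_p)
    fld = DropletFieldParams(chem=chem, nucleation_rate_coeff=1.0e-2)
    return fld, REFERENCE_PEPTIDE_MM, REFERENCE_VOLUME_UM3


def cell_reference(**overrides) -> CellParams:
    """Fuelled synthetic-cell reference: 10 mM peptide, 250 mM oil fuel,
    25 µm cell with fusion enabled."""
    return CellParams().with_(**overrides)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministically fan one global seed out to n module seeds.

    Uses numpy's SeedSequence; every derived seed is < 2³¹ so they stay
    portable across RNG back-ends.
    """
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


_SECTION_TYPES = {
    "chem_cycle": KineticParams,
    "size_control": DropletFieldParams,
    "cell_sim": CellParams,
    "synthetic_data": RenderOpts,
}


@dataclass
class RunConfig:
    """Validated nested configuration for end-to-end runs."""

    chem_cycle: KineticParams = field(default_factory=KineticParams)
    size_control: DropletFieldParams | None = None
    cell_sim: CellParams | None = None
    synthetic_data: RenderOpts = field(default_factory=RenderOpts)
    seed: int = 0
    out_dir: str = "actodrop_out"

    def __post_init__(self) -> None:
        if self.size_control is None:
            self.size_control = DropletFieldParams(chem=self.chem_cycle)
        if self.cell_sim is None:
            self.cell_sim = CellParams(field=self.size_control)

    def content_hash(self) -> str:
        """Stable hash of the full parameter content (for run reports)."""
        payload = json.dumps(_to_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def _build_section(cls, data: dict, context: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    # nested parameter objects are wired from already-built sections
    if cls is DropletFieldParams and "chem" not in kwargs:
        kwargs["chem"] = context.get("chem_cycle", KineticParams())
    if cls is CellParams and "field" not in kwargs:
        kwargs["field"] = context.get("size_control")
    if cls is RenderOpts and "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "k_exchange" in kwargs and kwargs["k_exchange"] in ("inf", ".inf", None):
        kwargs["k_exchange"] = float("inf")
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys reject."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(_SECTION_TYPES) | {"seed", "out_dir"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    context: dict = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            context[name] = _build_section(cls, raw[name] or {}, context)
    return RunConfig(
        chem_cycle=context.get("chem_cycle", KineticParams()),
        size_control=context.get("size_control"),
        cell_sim=context.get("cell_sim"),
        synthetic_data=context.get("synthetic_data", RenderOpts()),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "actodrop_out")),
    )


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
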