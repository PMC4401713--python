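"""Myosin isoform parameter sets.

An isoform is characterised by three structural parameters that vary
independently across the myosin superfamily: the attachment rate k_on, the
detachment rate k_off, and the power-stroke length delta_plus (equivalently a
lever length l and step angle theta, with delta_plus = l*sin(theta)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class IsoformConfig:
    """One myosin species.

    Attributes
    ----------
    label : str
        Human-readable name.
    k_on : float
        Attachment rate while a binding site is within reach, s^-1.
    k_off : float
        Detachment rate during the drag-stroke, s^-1.
    delta_plus : float
        Power-stroke length, nm.
    """

    label: str
    k_on: float
    k_off: float
    delta_plus: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "delta_plus"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @classmethod
    def from_lever(
        cls,
        label: str,
        k_on: float,
        k_off: float,
        lever_length: float,
        theta: float = 30.0,
    ) -> "IsoformConfig":
        """Build an isoform from lever length l (nm) and step angle theta (deg).

        delta_plus = l * sin(theta).
        """
        if not lever_length > 0:
            raise ValueError(f"lever_length must be strictly positive, got {lever_length!r}")
        if not 0 < theta < 90:
            raise ValueError(f"theta must lie in (0, 90) degrees, got {theta!r}")
        return cls(label, k_on, k_off, lever_length * math.sin(math.radians(theta)))

    def perturbed(self, label: str | None = None, **changes: float) -> "IsoformConfig":
        """Return a copy with one or more parameters replaced.

        Used to build the single-parameter extrapolations around a reference
        isoform (e.g. ``median.perturbed(k_on=1000.0)``).
        """
        fields = {"k_on": self.k_on, "k_off": self.k_off, "delta_plus": self.delta_plus}
        unknown = set(changes) - set(fields)
        if unknown:
            raise TypeError(f"unknown isoform parameters: {sorted(unknown)}")
        fields.update(changes)
        if label is None:
            label = self.label + "".join(
                f" {k}={changes[k]:g}" for k in ("k_on", "k_off", "delta_plus") if k in changes
            )
        return IsoformConfig(label, **fields)


def _load_builtin() -> dict[str, IsoformConfig]:
    raw = resources.files("myoswarm.data").joinpath("isoforms.json").read_text()
    return {
        rec["label"]: IsoformConfig(
            rec["label"], rec["k_on"], rec["k_off"], rec["delta_plus"]
        )
        for rec in json.loads(raw)
    }


#: Named isoforms used throughout the validation experiments.
#:   - "chicken skeletal": the empirically grounded datum isoform.
#:   - "median": centre of the extrapolated isoform family.
#:   - "baseline": starting point of the required-energy sweeps.
#:   - "low"/"high": all three parameters varied simultaneously.
ISOFORMS: dict[str, IsoformConfig] = _load_builtin()


def get_isoform(name: str) -> IsoformConfig:
    """Look up a named isoform from the built-in library."""
    try:
        return ISOFORMS[name]
    except KeyError:
        raise KeyError(
            f"unknown isoform {name!r}; available: {sorted(ISOFORMS)}"
        ) from None


def load_isoform_library(path: str | Path) -> dict[str, IsoformConfig]:
    """Load isoforms from a JSON file: a list of {label, k_on, k_off, delta_plus}."""
    records = json.loads(Path(path).read_text())
    return {
        rec["label"]: IsoformConfig(rec["label"], rec["k_on"], rec["k_off"], rec["delta_plus"])
        for rec in records
    }
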