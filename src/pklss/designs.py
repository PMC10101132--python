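"""Limited sampling strategy (LSS) definitions.

Each design is a set of nominal post-dose sampling times with windows:
the peak sample is drawn 15-30 min after dosing, the 4-h sample within
+/- 1 h, and the 24/48/72/96-h samples within +/- 4 h, reflecting that
real-world sampling never hits nominal times exactly. LSS11 and LSS12
take two samples within the same 48-h or 72-h window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SampleSpec", "SamplingDesign", "PEAK", "builtin_designs", "get_design"]


@dataclass(frozen=True)
class SampleSpec:
    """One nominal sampling time with its window and multiplicity."""

    nominal: float      # h post dose
    half_window: float  # h
    multiplicity: int = 1

    @property
    def window(self) -> tuple[float, float]:
        return (self.nominal - self.half_window, self.nominal + self.half_window)


# peak sample: uniform in 0.25-0.5 h (15-30 min post dose)
PEAK = SampleSpec(0.375, 0.125)

_WINDOW = {4.0: 1.0, 24.0: 4.0, 48.0: 4.0, 72.0: 4.0, 96.0: 4.0}


def _spec(t: float, mult: int = 1) -> SampleSpec:
    return SampleSpec(t, _WINDOW[t], mult)


@dataclass(frozen=True)
class SamplingDesign:
    design_id: str
    sample_specs: tuple[SampleSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"{self.design_id}: a design needs at least 2 samples")
        if not any(s.window[1] <= 0.5 for s in self.sample_specs):
            raise ValueError(f"{self.design_id}: every design includes a peak sample")

    @property
    def n_samples(self) -> int:
        return sum(s.multiplicity for s in self.sample_specs)

    @property
    def nominal_times(self) -> tuple[float, ...]:
        out: list[float] = []
        for s in self.sample_specs:
            out.extend([s.nominal] * s.multiplicity)
        return tuple(out)


def _design(design_id: str, times: list[float | tuple[float, int]]) -> SamplingDesign:
    specs: list[SampleSpec] = [PEAK]
    for t in times:
        if isinstance(t, tuple):
            specs.append(_spec(t[0], t[1]))
        else:
            specs.append(_spec(t))
    return SamplingDesign(design_id, tuple(specs))


def builtin_designs() -> dict[str, SamplingDesign]:
    """All evaluated designs; every one includes the peak (15-30 min) sample."""
    d = {
        # six samples
        "LSS1": _design("LSS1", [4.0, 24.0, 48.0, 72.0, 96.0]),
        # four samples
        "LSS2": _design("LSS2", [24.0, 48.0, 72.0]),
        "LSS3": _design("LSS3", [24.0, 48.0, 96.0]),
        "LSS4": _design("LSS4", [24.0, 72.0, 96.0]),
        "LSS5": _design("LSS5", [48.0, 72.0, 96.0]),
        # three samples
        "LSS6": _design("LSS6", [24.0, 48.0]),
        "LSS7": _design("LSS7", [48.0, 72.0]),
        "LSS8": _design("LSS8", [72.0, 96.0]),
        "LSS9": _design("LSS9", [24.0, 72.0]),
        "LSS10": _design("LSS10", [24.0, 96.0]),
        "LSS11": _design("LSS11", [(48.0, 2)]),
        "LSS12": _design("LSS12", [(72.0, 2)]),
        # two samples
        "LSS13": _design("LSS13", [24.0]),
        "LSS14": _design("LSS14", [48.0]),
        "LSS15": _design("LSS15", [72.0]),
        "LSS16": _design("LSS16", [96.0]),
        # SHL profiles (q48h dosing)
        "SHL_full": _design("SHL_full", [4.0, 24.0, 48.0]),
        "SHL_no4h": _design("SHL_no4h", [24.0, 48.0]),
    }
    return d


def get_design(design_id: str) -> SamplingDesign:
    designs = builtin_designs()
    if design_id not in designs:
        raise KeyError(f"unknown design '{design_id}'")
    return designs[design_id]
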