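"""Age-specific transition hazards for the illness-death model.

The three hazards — dementia incidence DI(x), mortality with dementia
DM(x) and mortality without dementia non-DM(x) — live on the integer age
grid 65..100, expressed per person-year. Cells may be missing (NaN) when
they come from observed data with zero exposure; the smoothing stage fills
ages 80+ and the life-table stage refuses incomplete grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AGE_LO = 65
AGE_HI = 100  # inclusive; exposure is truncated at the 100th birthday +1y
AGES = np.arange(AGE_LO, AGE_HI + 1)
N_AGES = AGES.size

TRANSITIONS = ("DI", "DM", "nonDM")

OBSERVED = "observed"
SMOOTHED = "smoothed"


@dataclass
class TransitionRates:
    """One sex x period stratum of hazards on the 65..100 age grid."""

    di: np.ndarray
    dm: np.ndarray
    nondm: np.ndarray
    sex: str | None = None
    period: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("di", "dm", "nondm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_AGES,):
                raise ValueError(
                    f"{name} must have {N_AGES} entries (ages {AGE_LO}..{AGE_HI}), "
                    f"got shape {arr.shape}"
                )
            with np.errstate(invalid="ignore"):
                if np.any(arr[np.isfinite(arr)] < 0):
                    raise ValueError(f"{name} contains negative rates")
            setattr(self, name, arr)
        if not self.provenance:
            self.provenance = {
                t: np.full(N_AGES, OBSERVED, dtype=object) for t in TRANSITIONS
            }

    @property
    def ages(self) -> np.ndarray:
        return AGES

    def series(self, transition: str) -> np.ndarray:
        return {"DI": self.di, "DM": self.dm, "nonDM": self.nondm}[transition]

    def is_complete(self) -> bool:
        return all(np.all(np.isfinite(self.series(t))) for t in TRANSITIONS)

    def copy(self) -> "TransitionRates":
        return TransitionRates(
            di=self.di.copy(),
            dm=self.dm.copy(),
            nondm=self.nondm.copy(),
            sex=self.sex,
            period=self.period,
            provenance={k: v.copy() for k, v in self.provenance.items()},
        )
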