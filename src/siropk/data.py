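"""Per-subject records and datasets for sparse TDM concentration data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .pk import DoseEvent

__all__ = ["SubjectData", "Dataset"]


@dataclass
class SubjectData:
    """One child's record: dosing history, observations and covariates.

    ``obs_conc`` may contain NaN for planned-but-unsimulated samples (a
    cohort fresh out of the generator); estimation requires them filled.
    """

    id: str
    weight: float
    doses: list[DoseEvent]
    obs_times: np.ndarray
    obs_conc: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"subject {self.id}: weight must be > 0")
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_conc = np.asarray(self.obs_conc, dtype=float)
        if self.obs_times.size == 0:
            raise ValueError(f"subject {self.id}: at least one observation required")
        if self.obs_times.shape != self.obs_conc.shape:
            raise ValueError(f"subject {self.id}: obs_times/obs_conc length mismatch")
        self.doses = sorted(self.doses, key=lambda d: d.time)

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)

    def has_concentrations(self) -> bool:
        return bool(np.all(np.isfinite(self.obs_conc)))


@dataclass
class Dataset:
    """An ordered collection of subjects with unique ids."""

    subjects: list[SubjectData]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectData]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> SubjectData:
        return self.subjects[i]

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for s in self.subjects:
            for k in s.covariates:
                if k not in names:
                    names.append(k)
        return names
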